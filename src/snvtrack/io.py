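"""Readers and writers for allele-count panels, species tables and results.

Two on-disk dialects are supported for allele counts:

``native-tsv``
    One TSV with the site key columns ``species_id, contig_id, position,
    ref_allele, alt_allele`` followed by a ``<sample>_ref`` / ``<sample>_alt``
    integer column pair per sample.  The sink is written first; on read it is
    taken from the ``sink=`` argument or defaults to the first sample pair.

``midas-snps``
    A directory of per-species subdirectories (or a single species directory)
    in the layout of MIDAS v1.2 ``snps`` output: ``snps_info.txt`` with
    ``site_id`` (``contig|position``) and ref/alt alleles, plus matching
    ``snps_ref_freq.txt`` and ``snps_depth.txt`` matrices.  Frequencies and
    depths are converted to integer counts with ``ref = round(ref_freq x
    depth)`` (round-half-to-even) and ``alt = depth - ref``; a sample missing
    a site (depth 0) simply contributes zero counts.

Coordinates are 1-based and inclusive throughout.  Multi-allelic rows (alleles
that are not single A/C/G/T characters) and rows with negative counts are
rejected at read time with a warning.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import (
    KEY_COLUMNS,
    VALID_ALLELES,
    AlleleCountPanel,
    ContributionTable,
    DuplicateSiteError,
    PanelFormatError,
)

__all__ = [
    "read_allele_table",
    "write_allele_table",
    "read_species_table",
    "write_species_table",
    "read_contributions",
    "write_contributions",
]


# --------------------------------------------------------------------- panels
def _sample_names_from_header(columns: list[str]) -> list[str]:
    samples: list[str] = []
    for col in columns:
        if col in KEY_COLUMNS:
            continue
        if col.endswith("_ref"):
            samples.append(col[: -len("_ref")])
        elif not col.endswith("_alt"):
            raise PanelFormatError(f"unrecognised column {col!r}")
    for s in samples:
        if f"{s}_alt" not in columns:
            raise PanelFormatError(f"missing column {s + '_alt'!r}")
    return samples


def _reject_malformed(df: pd.DataFrame, count_cols: list[str]) -> pd.DataFrame:
    """Drop rows with non-ACGT/multi-character alleles or negative counts."""
    ok = (
        df["ref_allele"].isin(VALID_ALLELES)
        & df["alt_allele"].isin(VALID_ALLELES)
        & (df["ref_allele"] != df["alt_allele"])
        & (df["position"] >= 1)
    )
    for col in count_cols:
        ok &= df[col] >= 0
    n_bad = int((~ok).sum())
    if n_bad:
        warnings.warn(f"rejected {n_bad} malformed row(s)", stacklevel=3)
    return df[ok]


def read_allele_table(
    path: str | Path,
    dialect: str = "native-tsv",
    sink: str | None = None,
) -> AlleleCountPanel:
    """Read an allele-count panel from disk.

    Parameters
    ----------
    path
        File (``native-tsv``) or directory (``midas-snps``) to read.
    dialect
        ``"native-tsv"`` or ``"midas-snps"``.
    sink
        Name of the sink sample.  Defaults to the first sample in the file;
        pass ``sink=""`` explicitly for a sources-only panel.
    """
    path = Path(path)
    if dialect == "native-tsv":
        return _read_native(path, sink)
    if dialect == "midas-snps":
        return _read_midas(path, sink)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_native(path: Path, sink: str | None) -> AlleleCountPanel:
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={"species_id": str, "contig_id": str})
    missing = [c for c in KEY_COLUMNS if c not in df.columns]
    if missing:
        raise PanelFormatError(f"missing column(s): {', '.join(missing)}")
    samples = _sample_names_from_header(list(df.columns))
    if not samples:
        raise PanelFormatError("no <sample>_ref/<sample>_alt column pairs found")
    count_cols = [f"{s}_{a}" for s in samples for a in ("ref", "alt")]
    df = _reject_malformed(df, count_cols)

    if sink is None:
        sink = samples[0]
    elif sink == "":
        sink = None
    elif sink not in samples:
        raise PanelFormatError(f"sink sample {sink!r} not found in header")
    sources = [s for s in samples if s != sink]

    dup = df.duplicated(subset=["species_id", "contig_id", "position"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise DuplicateSiteError(
            f"duplicate site: {row['species_id']}:{row['contig_id']}:{row['position']}"
        )
    return AlleleCountPanel(
        keys=df[KEY_COLUMNS],
        sink_name=sink,
        source_names=sources,
        sink_ref=df[f"{sink}_ref"].to_numpy() if sink else None,
        sink_alt=df[f"{sink}_alt"].to_numpy() if sink else None,
        source_ref=np.column_stack([df[f"{s}_ref"].to_numpy() for s in sources]),
        source_alt=np.column_stack([df[f"{s}_alt"].to_numpy() for s in sources]),
    )


def _read_midas_species(species_dir: Path) -> pd.DataFrame:
    info = pd.read_csv(species_dir / "snps_info.txt", sep="\t", dtype=str)
    for col in ("site_id", "ref_allele", "alt_allele"):
        if col not in info.columns:
            raise PanelFormatError(f"missing column(s): {col} (in {species_dir.name}/snps_info.txt)")
    freq = pd.read_csv(species_dir / "snps_ref_freq.txt", sep="\t", index_col="site_id")
    depth = pd.read_csv(species_dir / "snps_depth.txt", sep="\t", index_col="site_id")
    if list(freq.columns) != list(depth.columns):
        raise PanelFormatError("snps_ref_freq and snps_depth sample columns differ")
    info = info.set_index("site_id").loc[freq.index]
    contig_pos = info.index.to_series().str.rsplit("|", n=1, expand=True)
    depth_m = depth.to_numpy(dtype=float)
    # round-half-to-even, as numpy's rint implements
    ref_m = np.rint(np.nan_to_num(freq.to_numpy(dtype=float)) * depth_m).astype(np.int64)
    out = pd.DataFrame(
        {
            "species_id": species_dir.name,
            "contig_id": contig_pos[0].to_numpy(),
            "position": contig_pos[1].astype(int).to_numpy(),
            "ref_allele": info["ref_allele"].to_numpy(),
            "alt_allele": info["alt_allele"].to_numpy(),
        }
    )
    for j, sample in enumerate(freq.columns):
        out[f"{sample}_ref"] = ref_m[:, j]
        out[f"{sample}_alt"] = depth_m[:, j].astype(np.int64) - ref_m[:, j]
    return out


def _read_midas(path: Path, sink: str | None) -> AlleleCountPanel:
    if not path.is_dir():
        raise PanelFormatError(f"midas-snps dialect expects a directory, got {path}")
    if (path / "snps_info.txt").exists():
        species_dirs = [path]
    else:
        species_dirs = sorted(d for d in path.iterdir() if (d / "snps_info.txt").exists())
    if not species_dirs:
        raise PanelFormatError(f"no MIDAS snps output found under {path}")
    frames = [_read_midas_species(d) for d in species_dirs]
    df = pd.concat(frames, ignore_index=True)
    samples = _sample_names_from_header(list(df.columns))
    count_cols = [f"{s}_{a}" for s in samples for a in ("ref", "alt")]
    df = _reject_malformed(df, count_cols)
    if sink is None:
        sink = samples[0]
    elif sink == "":
        sink = None
    sources = [s for s in samples if s != sink]
    return AlleleCountPanel(
        keys=df[KEY_COLUMNS],
        sink_name=sink,
        source_names=sources,
        sink_ref=df[f"{sink}_ref"].to_numpy() if sink else None,
        sink_alt=df[f"{sink}_alt"].to_numpy() if sink else None,
        source_ref=np.column_stack([df[f"{s}_ref"].to_numpy() for s in sources]),
        source_alt=np.column_stack([df[f"{s}_alt"].to_numpy() for s in sources]),
    )


def write_allele_table(panel: AlleleCountPanel, path: str | Path) -> None:
    """Write a panel in the native TSV dialect (sink sample first)."""
    df = panel.keys.copy()
    if panel.sink_name is not None:
        df[f"{panel.sink_name}_ref"] = panel.sink_ref
        df[f"{panel.sink_name}_alt"] = panel.sink_alt
    for j, s in enumerate(panel.source_names):
        df[f"{s}_ref"] = panel.source_ref[:, j]
        df[f"{s}_alt"] = panel.source_alt[:, j]
    df.to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------- species tables
def read_species_table(path: str | Path) -> dict[str, dict[str, float]]:
    """Read a species x samples TSV and renormalise each sample column to 1.

    Returns a mapping ``sample -> {species_id -> relative abundance}``.
    Negative values raise; an all-zero sample column raises.
    """
    df = pd.read_csv(path, sep="\t", dtype={"species_id": str})
    if "species_id" not in df.columns:
        raise PanelFormatError("missing column(s): species_id")
    df = df.set_index("species_id")
    vals = df.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative abundance in species table")
    out: dict[str, dict[str, float]] = {}
    for sample in df.columns:
        col = df[sample].to_numpy(dtype=float)
        total = col.sum()
        if total <= 0:
            raise ValueError(f"sample {sample!r} has zero total abundance")
        out[sample] = dict(zip(df.index, col / total))
    return out


def write_species_table(
    abundance: dict[str, dict[str, float]], path: str | Path
) -> None:
    species = sorted({sp for ab in abundance.values() for sp in ab})
    df = pd.DataFrame(
        {sample: [ab.get(sp, 0.0) for sp in species] for sample, ab in abundance.items()},
        index=pd.Index(species, name="species_id"),
    )
    df.to_csv(path, sep="\t", float_format="%.10g")


# --------------------------------------------------------------- result files
def write_contributions(table: ContributionTable, path: str | Path) -> None:
    """Write a contribution table as TSV (sink, source, proportion)."""
    table.validate()
    df = table.data.copy()
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_contributions(path: str | Path) -> ContributionTable:
    df = pd.read_csv(path, sep="\t", dtype={"sink": str, "source": str})
    return ContributionTable(df)
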