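"""Core data model: per-site allele counts for one sink and J candidate sources.

The central container is :class:`AlleleCountPanel`, which holds a multi-species
collection of biallelic sites with read counts for one sink sample and an
ordered set of source samples, plus optional per-sample species relative
abundances.  Counts are stored column-wise in numpy arrays so that scoring and
the strain-sharing baselines can operate vectorised over all sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")

KEY_COLUMNS = ["species_id", "contig_id", "position", "ref_allele", "alt_allele"]


class PanelFormatError(ValueError):
    """A file or table does not conform to the panel format."""


class DuplicateSiteError(PanelFormatError):
    """The same (species, contig, position) appears more than once."""


@dataclass(frozen=True)
class SiteKey:
    """Identity of one biallelic genomic site.

    Coordinates are 1-based and inclusive, matching MIDAS site identifiers.
    """

    species_id: str
    contig_id: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for name in ("ref_allele", "alt_allele"):
            allele = getattr(self, name)
            if allele not in VALID_ALLELES:
                raise ValueError(f"{name} must be one of A/C/G/T, got {allele!r}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref_allele and alt_allele must differ")


@dataclass
class SiteAlleleCounts:
    """Read counts at one site: sink (n, m) plus per-source ref/alt vectors."""

    key: SiteKey
    sink_ref: int
    sink_alt: int
    source_ref: np.ndarray
    source_alt: np.ndarray

    def __post_init__(self) -> None:
        self.source_ref = np.asarray(self.source_ref, dtype=np.int64)
        self.source_alt = np.asarray(self.source_alt, dtype=np.int64)
        if self.source_ref.shape != self.source_alt.shape or self.source_ref.ndim != 1:
            raise ValueError("source_ref and source_alt must be 1-D and equally long")
        if self.source_ref.size < 1:
            raise ValueError("a site needs at least one source (J >= 1)")
        if self.sink_ref < 0 or self.sink_alt < 0:
            raise ValueError("sink counts must be non-negative")
        if (self.source_ref < 0).any() or (self.source_alt < 0).any():
            raise ValueError("source counts must be non-negative")

    @property
    def sink_depth(self) -> int:
        return self.sink_ref + self.sink_alt

    @property
    def source_depth(self) -> np.ndarray:
        return self.source_ref + self.source_alt


class AlleleCountPanel:
    """Sites x samples allele-count matrix for one source-tracking experiment.

    Parameters
    ----------
    keys
        DataFrame with columns ``species_id, contig_id, position, ref_allele,
        alt_allele`` (one row per site).
    sink_name
        Name of the sink sample, or ``None`` for a sources-only panel.
    source_names
        Ordered, unique source sample names (must not include the sink).
    sink_ref, sink_alt
        Length-S integer arrays (ignored / zeros when ``sink_name`` is None).
    source_ref, source_alt
        (S, J) integer arrays of per-source counts.
    species_abundance
        Optional mapping ``sample -> {species_id -> relative abundance}``;
        each sample's abundances must sum to 1 within 1e-6.
    """

    def __init__(
        self,
        keys: pd.DataFrame,
        sink_name: str | None,
        source_names: list[str],
        sink_ref: np.ndarray | None,
        sink_alt: np.ndarray | None,
        source_ref: np.ndarray,
        source_alt: np.ndarray,
        species_abundance: dict[str, dict[str, float]] | None = None,
    ) -> None:
        self.keys = keys.reset_index(drop=True)
        self.sink_name = sink_name
        self.source_names = list(source_names)
        n = len(self.keys)
        J = len(source_names)
        self.source_ref = np.asarray(source_ref, dtype=np.int64).reshape(n, J)
        self.source_alt = np.asarray(source_alt, dtype=np.int64).reshape(n, J)
        if sink_ref is None:
            sink_ref = np.zeros(n, dtype=np.int64)
        if sink_alt is None:
            sink_alt = np.zeros(n, dtype=np.int64)
        self.sink_ref = np.asarray(sink_ref, dtype=np.int64).reshape(n)
        self.sink_alt = np.asarray(sink_alt, dtype=np.int64).reshape(n)
        self.species_abundance = species_abundance
        self.validate()

    # ------------------------------------------------------------------ basic
    @property
    def n_sites(self) -> int:
        return len(self.keys)

    @property
    def n_sources(self) -> int:
        return len(self.source_names)

    @property
    def samples(self) -> list[str]:
        names = [] if self.sink_name is None else [self.sink_name]
        return names + self.source_names

    @property
    def sink_depth(self) -> np.ndarray:
        return self.sink_ref + self.sink_alt

    @property
    def source_depth(self) -> np.ndarray:
        return self.source_ref + self.source_alt

    def validate(self) -> None:
        missing = [c for c in KEY_COLUMNS if c not in self.keys.columns]
        if missing:
            raise PanelFormatError(f"missing key column(s): {', '.join(missing)}")
        n = self.n_sites
        if self.source_ref.shape != (n, self.n_sources) or self.source_alt.shape != (
            n,
            self.n_sources,
        ):
            raise ValueError("source count arrays must be (n_sites, n_sources)")
        if len(set(self.source_names)) != self.n_sources:
            raise ValueError("source names must be unique")
        if self.sink_name is not None and self.sink_name in self.source_names:
            raise ValueError("sink name must not appear among the sources")
        if (self.sink_ref < 0).any() or (self.sink_alt < 0).any():
            raise ValueError("sink counts must be non-negative")
        if (self.source_ref < 0).any() or (self.source_alt < 0).any():
            raise ValueError("source counts must be non-negative")
        if n:
            if (self.keys["position"] < 1).any():
                raise PanelFormatError("positions must be >= 1 (1-based coordinates)")
            bad = ~self.keys["ref_allele"].isin(VALID_ALLELES) | ~self.keys[
                "alt_allele"
            ].isin(VALID_ALLELES)
            if bad.any():
                raise PanelFormatError("alleles must be single nucleotides A/C/G/T")
            if (self.keys["ref_allele"] == self.keys["alt_allele"]).any():
                raise PanelFormatError("ref and alt alleles must differ")
            dup = self.keys.duplicated(subset=["species_id", "contig_id", "position"])
            if dup.any():
                first = self.keys.loc[dup.idxmax(), ["species_id", "contig_id", "position"]]
                raise DuplicateSiteError(
                    "duplicate site: "
                    f"{first['species_id']}:{first['contig_id']}:{first['position']}"
                )
        if self.species_abundance is not None:
            for sample, abund in self.species_abundance.items():
                vals = np.fromiter(abund.values(), dtype=float)
                if vals.size and abs(vals.sum() - 1.0) > 1e-6:
                    raise ValueError(
                        f"species abundances for {sample!r} sum to {vals.sum():.8f}, not 1"
                    )
                if vals.size and (vals < 0).any():
                    raise ValueError(f"negative species abundance for {sample!r}")

    # ------------------------------------------------------------------ access
    def site_key(self, i: int) -> SiteKey:
        row = self.keys.iloc[i]
        return SiteKey(
            species_id=row["species_id"],
            contig_id=row["contig_id"],
            position=int(row["position"]),
            ref_allele=row["ref_allele"],
            alt_allele=row["alt_allele"],
        )

    def site(self, i: int) -> SiteAlleleCounts:
        return SiteAlleleCounts(
            key=self.site_key(i),
            sink_ref=int(self.sink_ref[i]),
            sink_alt=int(self.sink_alt[i]),
            source_ref=self.source_ref[i].copy(),
            source_alt=self.source_alt[i].copy(),
        )

    def iter_sites(self):
        for i in range(self.n_sites):
            yield self.site(i)

    def counts_for(self, sample: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (ref, alt) count arrays for any sample (sink or source)."""
        if sample == self.sink_name:
            return self.sink_ref, self.sink_alt
        try:
            j = self.source_names.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in panel") from None
        return self.source_ref[:, j], self.source_alt[:, j]

    # ------------------------------------------------------------------ views
    def subset_sites(self, index: np.ndarray) -> "AlleleCountPanel":
        """Panel restricted to the sites selected by a boolean or integer index."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return AlleleCountPanel(
            keys=self.keys.iloc[index],
            sink_name=self.sink_name,
            source_names=self.source_names,
            sink_ref=self.sink_ref[index],
            sink_alt=self.sink_alt[index],
            source_ref=self.source_ref[index],
            source_alt=self.source_alt[index],
            species_abundance=self.species_abundance,
        )

    def select_sources(self, names: list[str]) -> "AlleleCountPanel":
        """Panel restricted to a subset of sources (order taken from `names`)."""
        idx = [self.source_names.index(n) for n in names]
        abund = None
        if self.species_abundance is not None:
            keep = set(names) | ({self.sink_name} if self.sink_name else set())
            abund = {s: a for s, a in self.species_abundance.items() if s in keep}
        return AlleleCountPanel(
            keys=self.keys,
            sink_name=self.sink_name,
            source_names=list(names),
            sink_ref=self.sink_ref,
            sink_alt=self.sink_alt,
            source_ref=self.source_ref[:, idx],
            source_alt=self.source_alt[:, idx],
            species_abundance=abund,
        )

    def swap_sink(self, source_name: str) -> "AlleleCountPanel":
        """Swap the roles of the sink and one source (for reverse tracking).

        The returned panel has ``source_name`` as its sink and the previous
        sink among the sources; counts are merely relabelled.
        """
        if self.sink_name is None:
            raise ValueError("panel has no sink to swap")
        j = self.source_names.index(source_name)
        names = list(self.source_names)
        names[j] = self.sink_name
        new_source_ref = self.source_ref.copy()
        new_source_alt = self.source_alt.copy()
        new_source_ref[:, j] = self.sink_ref
        new_source_alt[:, j] = self.sink_alt
        return AlleleCountPanel(
            keys=self.keys,
            sink_name=source_name,
            source_names=names,
            sink_ref=self.source_ref[:, j],
            sink_alt=self.source_alt[:, j],
            source_ref=new_source_ref,
            source_alt=new_source_alt,
            species_abundance=self.species_abundance,
        )

    def with_sink(self, sink_name: str, sink_ref: np.ndarray, sink_alt: np.ndarray) -> "AlleleCountPanel":
        return AlleleCountPanel(
            keys=self.keys,
            sink_name=sink_name,
            source_names=self.source_names,
            sink_ref=sink_ref,
            sink_alt=sink_alt,
            source_ref=self.source_ref,
            source_alt=self.source_alt,
            species_abundance=self.species_abundance,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"AlleleCountPanel(sink={self.sink_name!r}, J={self.n_sources}, "
            f"sites={self.n_sites}, species={self.keys['species_id'].nunique() if self.n_sites else 0})"
        )


@dataclass
class ContributionTable:
    """Estimated source contributions, one row per (sink, source-or-unknown)."""

    data: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sink", "source", "proportion"])
    )

    def __post_init__(self) -> None:
        required = {"sink", "source", "proportion"}
        if not required.issubset(self.data.columns):
            missing = required - set(self.data.columns)
            raise PanelFormatError(f"missing contribution column(s): {', '.join(sorted(missing))}")
        self.validate()

    def validate(self) -> None:
        if len(self.data) == 0:
            return
        props = self.data["proportion"].to_numpy(dtype=float)
        if ((props < -1e-9) | (props > 1 + 1e-9)).any():
            raise ValueError("proportions must lie in [0, 1]")
        sums = self.data.groupby("sink")["proportion"].sum()
        bad = sums[(sums - 1.0).abs() > 1e-6]
        if len(bad):
            raise ValueError(
                f"proportions for sink {bad.index[0]!r} sum to {bad.iloc[0]:.8f}, not 1"
            )

    @classmethod
    def from_estimates(cls, estimates) -> "ContributionTable":
        """Build from one or more SourceContributionEstimate objects."""
        if not isinstance(estimates, (list, tuple)):
            estimates = [estimates]
        rows = [
            {"sink": est.sink_name, "source": src, "proportion": p}
            for est in estimates
            for src, p in est.contributions.items()
        ]
        return cls(pd.DataFrame(rows, columns=["sink", "source", "proportion"]))
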