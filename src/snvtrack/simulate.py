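"""Synthetic source panels and simulated sink microbiomes with known truth.

The generator emulates mother-to-infant transmission experiments at the
allele-count level:

* Source communities share a base species-abundance profile (log-normal
  across species) with per-source log-normal variation, mimicking hosts
  drawn from one cohort.
* Per species, each biallelic site has an ancestral reference-allele
  frequency; each source carries a mostly clonal strain genotype derived
  from a shared ancestral genotype with per-source divergence, a small
  within-host polymorphic fraction, and slight frequency noise.  Read counts
  are binomial draws at Poisson depths scaled by species abundance.
* Which species colonise the simulated sink is governed by beta-distributed
  transmission probabilities centred on (a multiple of) each source's
  species abundance: one Bernoulli draw per source, and a single success
  transmits the species from every source carrying it.
* The sink's reads at each site of a transmitted species are allocated to
  the contributing sources (including one held-out "unknown" source)
  multinomially, with weights proportional to mixing proportion times that
  source's abundance of the species — exactly what pooling raw reads from
  the source samples at those proportions produces.  Allocated reads carry
  the reference allele binomially at the source's site frequency.

The held-out source's reads contribute to the sink but the source itself is
excluded from the emitted panel, providing ground truth for the unknown
component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import AlleleCountPanel

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "beta_params_from_moments",
    "generate_source_panel",
    "draw_transmissions",
    "simulate_sink",
    "simulate_experiment",
    "sample_mixture_proportions",
]

_NUCS = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for one simulated source-tracking experiment.

    ``n_sources`` counts the contributing sources *including* the held-out
    unknown one; ``known_proportions`` has length ``n_sources - 1`` and,
    together with ``unknown_proportion``, must sum to 1.
    """

    n_sources: int = 5
    known_proportions: tuple[float, ...] = (0.2, 0.2, 0.15, 0.15)
    unknown_proportion: float = 0.3
    transmission_mode: str = "high"  # {"high", "low"}
    transmission_variance: float = 0.1
    n_species: int = 20
    sites_per_species: int = 2000
    contig_length: int = 1_000_000
    sink_depth: float = 50.0  # mean per-site sink depth
    per_site_depth_mean: float = 50.0  # mean per-site source depth
    seed: int = 0
    # community / strain structure
    abundance_sigma: float = 1.5  # log-normal spread across species
    source_sigma: float = 0.6  # per-source log-normal abundance variation
    divergence: float = 0.3  # fraction of sites where a source's strain diverges
    het_fraction: float = 0.1  # within-host polymorphic fraction of sites
    allele_noise: float = 0.02  # SD of frequency noise around strain genotypes
    n_background: int = 0  # extra unrelated samples (marker-allele background)
    sink_name: str = "sink"

    def __post_init__(self) -> None:
        if self.n_sources < 2:
            raise ValueError("need at least one known source plus the unknown")
        if len(self.known_proportions) != self.n_sources - 1:
            raise ValueError("known_proportions must have length n_sources - 1")
        total = sum(self.known_proportions) + self.unknown_proportion
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, not 1")
        if self.transmission_mode not in ("high", "low"):
            raise ValueError("transmission_mode must be 'high' or 'low'")
        if self.transmission_variance <= 0:
            raise ValueError("transmission_variance must be > 0")
        if self.n_species * self.sites_per_species == 0:
            raise ValueError("panel must contain at least one site")

    @property
    def source_names(self) -> list[str]:
        """All contributing sources; the last one is held out as unknown."""
        return [f"source_{i + 1:02d}" for i in range(self.n_sources)]

    @property
    def known_sources(self) -> list[str]:
        return self.source_names[:-1]

    @property
    def unknown_source(self) -> str:
        return self.source_names[-1]

    @property
    def background_names(self) -> list[str]:
        return [f"background_{i + 1:02d}" for i in range(self.n_background)]


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated sink."""

    proportions: dict[str, float]  # by source name, incl. the held-out source
    unknown_source: str
    transmission_mask: dict[str, bool]
    config: SimulationConfig
    realized_read_fractions: dict[str, float] = field(default_factory=dict)

    def estimation_truth(self) -> dict[str, float]:
        """Truth keyed the way estimators report it (held-out -> 'unknown')."""
        out = {
            name: pi
            for name, pi in self.proportions.items()
            if name != self.unknown_source
        }
        out["unknown"] = self.proportions[self.unknown_source]
        return out


def beta_params_from_moments(mean: float, variance: float) -> tuple[float, float]:
    """Beta shape parameters (a, b) from a mean and variance.

    The variance of a Beta distribution cannot exceed ``mean * (1 - mean)``;
    an infeasible request is clamped to 95% of that bound (keeping the mean
    exact and the distribution proper).
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean must lie strictly in (0, 1), got {mean}")
    if variance <= 0:
        raise ValueError("variance must be > 0")
    bound = mean * (1.0 - mean)
    if variance >= bound:
        variance = 0.95 * bound
    nu = bound / variance - 1.0
    return mean * nu, (1.0 - mean) * nu


# ---------------------------------------------------------------- generation
def _abundance_matrix(config: SimulationConfig, rng: np.random.Generator, n_samples: int) -> np.ndarray:
    base = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=config.n_species)
    raw = base[None, :] * rng.lognormal(
        mean=0.0, sigma=config.source_sigma, size=(n_samples, config.n_species)
    )
    return raw / raw.sum(axis=1, keepdims=True)


def generate_source_panel(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[AlleleCountPanel, dict]:
    """Generate the sources-only panel plus the latent generator state.

    Returns ``(panel, latent)`` where ``latent`` holds the per-source latent
    allele frequencies ``p`` (sites x samples), the ancestral frequencies
    ``ancestral_freq``, and the species-abundance matrix used for depths.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    names = config.source_names + config.background_names
    n_samples = len(names)
    abund = _abundance_matrix(config, rng, n_samples)

    n_sp, n_sites = config.n_species, config.sites_per_species
    species_ids = [f"species_{c + 1:03d}" for c in range(n_sp)]
    keys_frames = []
    q_all = np.empty(n_sp * n_sites)
    for c, sp in enumerate(species_ids):
        positions = np.sort(rng.choice(config.contig_length, size=n_sites, replace=False)) + 1
        ref_idx = rng.integers(0, 4, size=n_sites)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
        keys_frames.append(
            pd.DataFrame(
                {
                    "species_id": sp,
                    "contig_id": f"{sp}_c1",
                    "position": positions,
                    "ref_allele": _NUCS[ref_idx],
                    "alt_allele": _NUCS[alt_idx],
                }
            )
        )
        q_all[c * n_sites : (c + 1) * n_sites] = rng.uniform(0.05, 0.95, size=n_sites)
    keys = pd.concat(keys_frames, ignore_index=True)
    S = len(keys)
    species_index = np.repeat(np.arange(n_sp), n_sites)

    g0 = rng.random(S) < q_all
    p = np.empty((S, n_samples))
    for j in range(n_samples):
        g = np.where(rng.random(S) < config.divergence, rng.random(S) < q_all, g0)
        pj = np.clip(
            g.astype(float) + rng.normal(0.0, config.allele_noise, size=S), 1e-6, 1.0 - 1e-6
        )
        if config.het_fraction > 0:
            het = rng.random(S) < config.het_fraction
            pj[het] = rng.uniform(0.2, 0.8, size=int(het.sum()))
        p[:, j] = pj

    # depth scales with how abundant the species is in that sample
    scale = abund[:, species_index].T * n_sp  # (S, n_samples), mean 1 over species
    depth = rng.poisson(config.per_site_depth_mean * scale)
    ref = rng.binomial(depth, p)
    alt = depth - ref

    panel = AlleleCountPanel(
        keys=keys,
        sink_name=None,
        source_names=names,
        sink_ref=None,
        sink_alt=None,
        source_ref=ref,
        source_alt=alt,
        species_abundance={
            name: dict(zip(species_ids, abund[j])) for j, name in enumerate(names)
        },
    )
    latent = {
        "p": p,
        "ancestral_freq": q_all,
        "abundance": abund,
        "sample_names": names,
        "species_ids": species_ids,
        "species_index": species_index,
    }
    return panel, latent


def draw_transmissions(
    source_abundances: np.ndarray,
    mode: str,
    variance: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-species transmission mask from beta-distributed probabilities.

    ``source_abundances`` is (J, n_species).  For each (source, species) a
    transmission probability is drawn from a Beta with mean equal to the
    species abundance (``mode='high'``) or 0.1 times it (``mode='low'``) and
    the requested variance; one Bernoulli draw per source follows, and any
    success transmits the species (from all sources carrying it).
    """
    ab = np.asarray(source_abundances, dtype=float)
    mu = np.clip(ab if mode == "high" else 0.1 * ab, 1e-9, 1.0 - 1e-9)
    transmitted = np.zeros(ab.shape[1], dtype=bool)
    for j in range(ab.shape[0]):
        for c in range(ab.shape[1]):
            a, b = beta_params_from_moments(mu[j, c], variance)
            prob = rng.beta(a, b)
            if rng.random() < prob:
                transmitted[c] = True
    return transmitted


def simulate_sink(
    panel: AlleleCountPanel,
    latent: dict,
    truth: SyntheticTruth,
    rng: np.random.Generator,
    renormalize: bool = True,
) -> tuple[AlleleCountPanel, SyntheticTruth]:
    """Draw the sink sample and return the emitted panel plus completed truth.

    Sink reads for each transmitted species are split among the contributing
    sources with weights proportional to ``proportion x abundance`` (or, with
    ``renormalize=False``, allocated by raw proportions with reads assigned
    to non-carrying sources discarded).  The held-out unknown source's reads
    enter the sink but the source is dropped from the emitted panel.
    """
    config = truth.config
    names = list(truth.proportions)
    pi = np.array([truth.proportions[s] for s in names])
    sample_names = latent["sample_names"]
    cols = [sample_names.index(s) for s in names]
    abund = latent["abundance"][cols]  # (J, n_species)
    p = latent["p"][:, cols]  # (S, J)
    species_index = latent["species_index"]
    species_ids = latent["species_ids"]
    S = panel.n_sites

    t_mask = np.array([truth.transmission_mask[sp] for sp in species_ids])
    sink_ref = np.zeros(S, dtype=np.int64)
    sink_alt = np.zeros(S, dtype=np.int64)
    reads_per_source = dict.fromkeys(names, 0)

    # each source contributes (in expectation) exactly its mixing proportion of
    # the sink's reads, drawn from its transmitted species -- the abundances
    # are therefore renormalised per source over the transmitted species, as
    # pooling reads from real source samples at fixed proportions does
    abund = abund.copy()
    carried = abund * t_mask[None, :]
    row_tot = carried.sum(axis=1, keepdims=True)
    abund = np.divide(carried, row_tot, out=np.zeros_like(carried), where=row_tot > 0)
    W = (pi[:, None] * abund).sum(axis=0)  # (n_species,) mixture species weight
    active = t_mask & (W > 0)
    skipped = t_mask & (W <= 0)
    if skipped.any():
        warnings.warn(
            f"{int(skipped.sum())} transmitted species carried by no contributing source; skipped"
        )
    if active.any():
        mean_w = W[active].mean()
        for c in np.flatnonzero(active):
            sites = np.flatnonzero(species_index == c)
            if renormalize:
                weights = pi * abund[:, c] / W[c]
            else:
                weights = pi
            depth = rng.poisson(config.sink_depth * W[c] / mean_w, size=sites.size)
            alloc = rng.multinomial(depth, weights)  # (n_sites_c, J)
            if not renormalize:
                alloc[:, abund[:, c] <= 0] = 0  # discard reads from non-carriers
            refs = rng.binomial(alloc, p[sites])
            sink_ref[sites] = refs.sum(axis=1)
            sink_alt[sites] = (alloc - refs).sum(axis=1)
            for j, name in enumerate(names):
                reads_per_source[name] += int(alloc[:, j].sum())

    total = sum(reads_per_source.values())
    truth.realized_read_fractions = {
        s: (reads_per_source[s] / total if total else 0.0) for s in names
    }

    with_sink = panel.with_sink(config.sink_name, sink_ref, sink_alt)
    # realized sink species abundances, for species-level source tracking
    sink_depth = sink_ref + sink_alt
    sp_reads = np.bincount(species_index, weights=sink_depth, minlength=len(species_ids))
    if with_sink.species_abundance is not None and sp_reads.sum() > 0:
        with_sink.species_abundance = dict(with_sink.species_abundance)
        with_sink.species_abundance[config.sink_name] = dict(
            zip(species_ids, sp_reads / sp_reads.sum())
        )
    emitted = with_sink.select_sources(
        [s for s in with_sink.source_names if s != truth.unknown_source]
    )
    return emitted, truth


def sample_mixture_proportions(
    n_known: int,
    rng: np.random.Generator,
    unknown_range: tuple[float, float] = (0.10, 0.90),
    known_min: float = 0.01,
    known_max: float = 0.90,
) -> tuple[tuple[float, ...], float]:
    """Draw (known proportions, unknown proportion) from the study ranges.

    The unknown share is uniform on its range (upper-bounded so every known
    source can receive at least ``known_min``); the knowns split the
    remainder by a Dirichlet draw shifted to respect the lower bound.
    """
    hi = min(unknown_range[1], 1.0 - 2 * known_min * n_known)
    u = rng.uniform(unknown_range[0], hi)
    remainder = 1.0 - u - known_min * n_known
    known = known_min + rng.dirichlet(np.ones(n_known)) * remainder
    known = np.minimum(known, known_max)
    known *= (1.0 - u) / known.sum()
    return tuple(float(k) for k in known), float(u)


def simulate_experiment(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[AlleleCountPanel, SyntheticTruth, dict]:
    """Generate sources, transmissions and the sink in one call.

    Returns the emitted panel (sink + known sources + any background samples;
    the held-out unknown source removed), the completed truth manifest and
    the latent generator state.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    panel, latent = generate_source_panel(config, rng)
    contributing = config.source_names
    cols = [latent["sample_names"].index(s) for s in contributing]
    # a sink must contain at least one species to be a trackable instance;
    # under low transmission the mask can come up empty, so redraw it
    for _ in range(10_000):
        t_mask = draw_transmissions(
            latent["abundance"][cols], config.transmission_mode, config.transmission_variance, rng
        )
        if t_mask.any():
            break
    else:  # pragma: no cover - probability ~0 under any usable config
        raise RuntimeError("no species transmitted after 10000 transmission draws")
    proportions = dict(zip(config.known_sources, config.known_proportions))
    proportions[config.unknown_source] = config.unknown_proportion
    truth = SyntheticTruth(
        proportions=proportions,
        unknown_source=config.unknown_source,
        transmission_mask=dict(zip(latent["species_ids"], t_mask)),
        config=config,
    )
    return (*simulate_sink(panel, latent, truth, rng), latent)
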