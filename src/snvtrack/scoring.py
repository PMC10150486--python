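"""Signature-SNV selection by binomial likelihood ratio.

For every filtered site and every candidate source *i* two hypotheses are
compared for the sink's allele counts (n reference reads, m alternative
reads):

* Hypothesis 1 — source *i* alone explains the sink, so the sink reference
  allele frequency is that source's frequency, theta = p_i.
* Hypothesis 2 — the remaining sources jointly explain the sink, with
  theta = sum_{j != i} alpha_j p_j for mixture weights alpha on the simplex.

Each hypothesis is scored with the binomial log-likelihood
``LL(theta) = n*log(theta) + m*log(1 - theta)`` and the per-source
log-likelihood ratio is ``l1 - l2``.  The signature score of a site is the
maximum ratio over sources; sites scoring more than ``sd_multiplier`` standard
deviations above the mean within a genomic window are selected as signature
SNVs, and sites carrying an allele seen in the sink but in none of the
covered sources are rescued into the set regardless of score (they indicate
an unknown source).

The constrained Hypothesis-2 fit has a closed form: ``LL`` is concave in
theta, and as alpha ranges over the simplex theta sweeps exactly the interval
``[min_j p_j, max_j p_j]``, so the optimum is the unconstrained MLE
``n/(n+m)`` clipped into that interval, attained by a mixture of the two
extreme sources.  A numerical simplex optimiser is therefore unnecessary (and
the closed form is exact); equivalence is enforced against grid-search and
SLSQP oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import AlleleCountPanel, SiteAlleleCounts, SiteKey

EPSILON = 1e-6

__all__ = [
    "FilterConfig",
    "MixtureHypothesisFit",
    "SiteScore",
    "SignatureSet",
    "filter_sites",
    "binomial_log_likelihood",
    "fit_excluded_mixture",
    "score_site",
    "score_panel",
    "select_signature_snvs",
    "compute_signatures",
]


@dataclass
class FilterConfig:
    """Coverage filters and selection thresholds.

    min_site_depth
        Minimum read depth required in the sink, and in a source for that
        source to participate at a site (10 by default; 5 for low-coverage
        data such as environmental samples).
    min_reads_per_allele_if_biallelic
        A sink-biallelic site (both alleles observed) must have at least this
        many reads on each allele, i.e. "more than one read" = 2.
    window_size
        Genomic window (bp) within which the score mean/SD are computed.
    sd_multiplier
        Selection threshold: score must exceed mean + sd_multiplier * SD.
    global_threshold
        If True, use one mean/SD over all scored sites instead of per-window.
    rescue_sink_unique
        If True, sites with an allele unique to the sink are always selected.
    """

    min_site_depth: int = 10
    min_reads_per_allele_if_biallelic: int = 2
    window_size: int = 200_000
    sd_multiplier: float = 2.0
    global_threshold: bool = False
    rescue_sink_unique: bool = True

    def __post_init__(self) -> None:
        if self.min_site_depth < 1:
            raise ValueError("min_site_depth must be >= 1")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")


@dataclass
class MixtureHypothesisFit:
    """Result of the constrained Hypothesis-2 fit at one site.

    ``alpha`` holds one weight per non-focal source (aligned with the indices
    in ``source_indices``); ``theta_hat`` is the implied sink reference-allele
    frequency and ``loglik`` the binomial log-likelihood at the optimum.
    """

    theta_hat: float
    alpha: np.ndarray
    loglik: float
    source_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


@dataclass
class SiteScore:
    key: SiteKey
    per_source_llr: np.ndarray  # NaN where the source fails coverage
    score: float
    best_source: int
    sink_unique: bool


@dataclass
class SignatureSet:
    """Selected signature SNVs plus per-window audit statistics."""

    selected: list[SiteKey]
    selected_mask: np.ndarray
    per_window_stats: pd.DataFrame
    rescue_count: int

    def __len__(self) -> int:
        return len(self.selected)


# ------------------------------------------------------------------ filtering
def filter_sites(
    panel: AlleleCountPanel, config: FilterConfig | None = None
) -> tuple[AlleleCountPanel, np.ndarray]:
    """Apply coverage filters; return the retained panel and passing-source mask.

    A site is retained iff the sink has depth >= ``min_site_depth``, at least
    one source has depth >= ``min_site_depth``, and — when the sink is
    biallelic — each sink allele carries >= ``min_reads_per_allele_if_biallelic``
    reads.  The returned boolean mask has shape (n_retained_sites, J) and
    records which sources pass the depth requirement at each retained site.
    """
    config = config or FilterConfig()
    sink_depth = panel.sink_depth
    source_depth = panel.source_depth
    source_pass = source_depth >= config.min_site_depth
    keep = (sink_depth >= config.min_site_depth) & source_pass.any(axis=1)
    biallelic = (panel.sink_ref > 0) & (panel.sink_alt > 0)
    k = config.min_reads_per_allele_if_biallelic
    keep &= ~biallelic | ((panel.sink_ref >= k) & (panel.sink_alt >= k))
    return panel.subset_sites(keep), source_pass[keep]


# ---------------------------------------------------------------- likelihoods
def binomial_log_likelihood(
    theta_hat: float, n: int, m: int, epsilon: float = EPSILON
) -> float:
    """``n*log(theta) + m*log(1-theta)`` with theta clipped into [eps, 1-eps]."""
    if n < 0 or m < 0:
        raise ValueError("read counts must be non-negative")
    if n == 0 and m == 0:
        raise ValueError("undefined site: no sink reads (filter before scoring)")
    theta = min(max(theta_hat, epsilon), 1.0 - epsilon)
    return n * np.log(theta) + m * np.log1p(-theta)


def fit_excluded_mixture(
    site: SiteAlleleCounts,
    focal_source: int,
    passing_mask: np.ndarray,
    epsilon: float = EPSILON,
) -> MixtureHypothesisFit:
    """Maximise the sink log-likelihood over convex mixtures of non-focal sources.

    The mixture frequency theta = sum alpha_j p_j spans [min p_j, max p_j], on
    which the binomial log-likelihood is concave with unconstrained optimum
    n/(n+m); the constrained optimum is that value clipped into the hull, and
    a maximising alpha places weight on (at most) the two extreme sources.
    With no passing non-focal source the degenerate fit loglik = 0 is returned
    (the single-source l2 = 0 rule).
    """
    passing_mask = np.asarray(passing_mask, dtype=bool)
    nonfocal = np.flatnonzero(passing_mask)
    nonfocal = nonfocal[nonfocal != focal_source]
    if nonfocal.size == 0:
        return MixtureHypothesisFit(
            theta_hat=np.nan, alpha=np.array([]), loglik=0.0, source_indices=nonfocal
        )
    depth = site.source_depth[nonfocal].astype(float)
    p = np.clip(site.source_ref[nonfocal] / depth, epsilon, 1.0 - epsilon)
    n, m = site.sink_ref, site.sink_alt
    lo, hi = float(p.min()), float(p.max())
    theta = min(max(n / (n + m), lo), hi)
    alpha = np.zeros(nonfocal.size)
    if hi - lo < 1e-15:
        alpha[:] = 1.0 / nonfocal.size
    else:
        i_lo, i_hi = int(np.argmin(p)), int(np.argmax(p))
        w_hi = (theta - lo) / (hi - lo)
        alpha[i_lo] = 1.0 - w_hi
        alpha[i_hi] = w_hi
    return MixtureHypothesisFit(
        theta_hat=theta,
        alpha=alpha,
        loglik=binomial_log_likelihood(theta, n, m, epsilon),
        source_indices=nonfocal,
    )


def score_site(
    site: SiteAlleleCounts,
    passing_mask: np.ndarray,
    epsilon: float = EPSILON,
) -> SiteScore:
    """Per-source log-likelihood ratios and the site's signature score.

    For each source passing coverage, l1 evaluates the sink counts at that
    source's allele frequency and l2 at the best mixture of the remaining
    passing sources; the score is the maximum of l1 - l2 over sources.  The
    ``sink_unique`` flag marks sites where an allele with sink reads has zero
    reads in every passing source.
    """
    passing_mask = np.asarray(passing_mask, dtype=bool)
    J = site.source_ref.size
    llr = np.full(J, np.nan)
    n, m = site.sink_ref, site.sink_alt
    depth = site.source_depth.astype(float)
    for i in range(J):
        if not passing_mask[i]:
            continue
        p_i = np.clip(site.source_ref[i] / depth[i], epsilon, 1.0 - epsilon)
        l1 = binomial_log_likelihood(p_i, n, m, epsilon)
        l2 = fit_excluded_mixture(site, i, passing_mask, epsilon).loglik
        llr[i] = l1 - l2
    if np.all(np.isnan(llr)):
        raise ValueError("no source passes coverage; site should be filtered upstream")
    score = float(np.nanmax(llr))
    best = int(np.nanargmax(llr))
    ref_unique = n > 0 and not (site.source_ref[passing_mask] > 0).any()
    alt_unique = m > 0 and not (site.source_alt[passing_mask] > 0).any()
    return SiteScore(
        key=site.key,
        per_source_llr=llr,
        score=score,
        best_source=best,
        sink_unique=bool(ref_unique or alt_unique),
    )


def score_panel(
    panel: AlleleCountPanel,
    passing_mask: np.ndarray,
    epsilon: float = EPSILON,
) -> pd.DataFrame:
    """Vectorised scoring of all sites in a (pre-filtered) panel.

    Returns a DataFrame with the site key columns plus ``llr_<source>`` per
    source, ``score``, ``best_source`` and ``sink_unique``; equivalent to
    calling :func:`score_site` on every site.
    """
    S, J = panel.n_sites, panel.n_sources
    mask = np.asarray(passing_mask, dtype=bool).reshape(S, J)
    n = panel.sink_ref.astype(float)
    m = panel.sink_alt.astype(float)
    depth = panel.source_depth.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.clip(panel.source_ref / depth, epsilon, 1.0 - epsilon)
    p_masked_min = np.where(mask, p, np.inf)
    p_masked_max = np.where(mask, p, -np.inf)
    mle = n / (n + m)

    llr = np.full((S, J), np.nan)
    for i in range(J):
        mi = mask[:, i]
        if not mi.any():
            continue
        l1 = n * np.log(p[:, i]) + m * np.log1p(-p[:, i])
        # extremes of the non-focal passing frequencies
        lo = np.min(np.delete(p_masked_min, i, axis=1), axis=1)
        hi = np.max(np.delete(p_masked_max, i, axis=1), axis=1)
        has_nonfocal = np.isfinite(lo)
        theta = np.clip(mle, lo, hi)
        theta = np.clip(theta, epsilon, 1.0 - epsilon)
        l2 = np.where(
            has_nonfocal, n * np.log(theta) + m * np.log1p(-theta), 0.0
        )
        llr[:, i] = np.where(mi, l1 - l2, np.nan)

    score = np.nanmax(llr, axis=1)
    best = np.nanargmax(np.nan_to_num(llr, nan=-np.inf), axis=1)
    ref_unique = (panel.sink_ref > 0) & ~np.any((panel.source_ref > 0) & mask, axis=1)
    alt_unique = (panel.sink_alt > 0) & ~np.any((panel.source_alt > 0) & mask, axis=1)

    out = panel.keys.copy()
    for i, name in enumerate(panel.source_names):
        out[f"llr_{name}"] = llr[:, i]
    out["score"] = score
    out["best_source"] = best
    out["sink_unique"] = ref_unique | alt_unique
    return out


# ------------------------------------------------------------------ selection
def select_signature_snvs(
    scores: pd.DataFrame, config: FilterConfig | None = None
) -> SignatureSet:
    """Windowed 2-SD thresholding of signature scores, plus sink-unique rescue.

    Scores are grouped per (species, contig) into ``window_size``-bp windows
    (window index = floor((position - 1) / window_size)); a site is selected
    when its score strictly exceeds the window mean plus ``sd_multiplier``
    population standard deviations.  Windows holding a single site (SD 0)
    therefore select nothing.  Sink-unique sites are added regardless of score
    when rescue is enabled.
    """
    config = config or FilterConfig()
    scores = scores.reset_index(drop=True)
    window = (scores["position"] - 1) // config.window_size
    if config.global_threshold:
        group_keys = [np.zeros(len(scores), dtype=int)]
    else:
        group_keys = [scores["species_id"], scores["contig_id"], window]
    grouped = scores.groupby(group_keys, sort=False)["score"] if len(scores) else None

    if grouped is not None:
        stats = grouped.agg(mean="mean", sd=lambda s: float(np.std(s, ddof=0)), count="size")
        threshold = grouped.transform("mean") + config.sd_multiplier * grouped.transform(
            lambda s: float(np.std(s, ddof=0))
        )
        by_score = scores["score"] > threshold
    else:
        stats = pd.DataFrame(columns=["mean", "sd", "count"])
        by_score = pd.Series(dtype=bool)

    rescued = (
        scores["sink_unique"].astype(bool)
        if config.rescue_sink_unique and len(scores)
        else pd.Series(False, index=scores.index, dtype=bool)
    )
    selected_mask = (by_score | rescued).to_numpy(dtype=bool) if len(scores) else np.array([], dtype=bool)
    rescue_count = int((rescued & ~by_score).sum()) if len(scores) else 0

    selected = [
        SiteKey(
            species_id=row.species_id,
            contig_id=row.contig_id,
            position=int(row.position),
            ref_allele=row.ref_allele,
            alt_allele=row.alt_allele,
        )
        for row in scores[selected_mask].itertuples()
    ]
    if not config.global_threshold and grouped is not None:
        stats.index.set_names(["species_id", "contig_id", "window"], inplace=True)
    return SignatureSet(
        selected=selected,
        selected_mask=selected_mask,
        per_window_stats=stats.reset_index() if len(stats) else stats,
        rescue_count=rescue_count,
    )


def compute_signatures(
    panel: AlleleCountPanel, config: FilterConfig | None = None
) -> tuple[AlleleCountPanel, SignatureSet, pd.DataFrame]:
    """Filter, score and select in one call.

    Returns the filtered panel, the signature set (mask aligned with the
    filtered panel) and the per-site score table.
    """
    config = config or FilterConfig()
    filtered, mask = filter_sites(panel, config)
    scores = score_panel(filtered, mask)
    signatures = select_signature_snvs(scores, config)
    return filtered, signatures, scores
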