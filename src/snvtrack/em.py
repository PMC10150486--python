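"""Source-contribution estimation by expectation-maximisation.

The sink's feature counts (signature-SNV allele counts, or species
pseudo-counts) are modelled as a multinomial mixture over J known sources
plus one unknown source:

    x ~ Multinomial(N, sum_k alpha_k * gamma_k),      k = 1..J+1

where alpha is the simplex of source contributions and gamma_k the k-th
source's distribution over features.  Each known source additionally
contributes its own observed counts y_j ~ Multinomial(N_j, gamma_j), so its
feature distribution is informed jointly by the source sample and by the
sink reads attributed to it in the E-step.  The unknown source has no
observed sample; its distribution is estimated solely from its E-step share
of the sink, which lets it absorb sink reads that no known source can
explain.

EM updates (z_kf = expected sink reads at feature f assigned to source k):

    E-step:  z_kf = x_f * alpha_k gamma_kf / sum_l alpha_l gamma_lf
    M-step:  alpha_k   proportional to sum_f z_kf
             gamma_jf  proportional to y_jf + z_jf     (known j)
             gamma_uf  proportional to z_uf            (unknown)

The joint log-likelihood (sink term plus source terms) is non-decreasing
under these updates and is asserted to be so at run time.  With duplicate or
highly overlapping sources the optimum is not unique; the fixed point reached
from the deterministic start (uniform alpha, empirical gamma for known
sources, uniform gamma for the unknown) is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import AlleleCountPanel
from .scoring import SignatureSet

UNKNOWN = "unknown"

__all__ = [
    "FeatureMatrix",
    "EMConfig",
    "FeastModelState",
    "SourceContributionEstimate",
    "build_snv_features",
    "build_species_features",
    "estimate_contributions",
]


class EmptySignatureSetError(ValueError):
    pass


@dataclass
class FeatureMatrix:
    """Counts over F features for the sink and J sources.

    ``feature_sites`` and ``feature_groups`` optionally record which genomic
    site and which species each feature belongs to (the two allele-count
    features of one SNV share a site; all of a species' features share a
    group).  When present they let the estimator reason at the site and
    species level; when absent each feature is its own site and group.
    """

    feature_ids: list[str]
    sink_counts: np.ndarray  # (F,)
    source_counts: np.ndarray  # (J, F)
    source_names: list[str]
    sink_name: str = "sink"
    feature_sites: list[str] | None = None
    feature_groups: list[str] | None = None

    def __post_init__(self) -> None:
        self.sink_counts = np.asarray(self.sink_counts, dtype=np.int64)
        self.source_counts = np.asarray(self.source_counts, dtype=np.int64).reshape(
            len(self.source_names), -1
        )
        F = self.sink_counts.size
        if F < 1:
            raise ValueError("feature matrix must have at least one feature (F >= 1)")
        if len(self.feature_ids) != F or self.source_counts.shape[1] != F:
            raise ValueError("feature_ids, sink_counts and source_counts disagree on F")
        if (self.sink_counts < 0).any() or (self.source_counts < 0).any():
            raise ValueError("counts must be non-negative")
        dead = (self.sink_counts == 0) & (self.source_counts == 0).all(axis=0)
        if dead.any():
            raise ValueError("features with all-zero counts must be dropped")
        for name in ("feature_sites", "feature_groups"):
            val = getattr(self, name)
            if val is not None and len(val) != F:
                raise ValueError(f"{name} must have length F")


@dataclass
class EMConfig:
    tol: float = 1e-6  # relative log-likelihood change for convergence
    max_iter: int = 1000
    n_restarts: int = 1  # restart 0 is the deterministic start
    seed: int = 0
    rarefy: bool = False  # opt-in: subsample every sample to the minimum depth


@dataclass
class FeastModelState:
    alpha: np.ndarray  # (J+1,) known sources then unknown
    gamma: np.ndarray  # (J+1, F) row-stochastic
    loglik: float
    n_iter: int
    converged: bool


@dataclass
class SourceContributionEstimate:
    sink_name: str
    contributions: dict[str, float] = field(default_factory=dict)

    def as_array(self, order: list[str]) -> np.ndarray:
        return np.array([self.contributions[k] for k in order])


# ------------------------------------------------------------------ features
def build_snv_features(
    panel: AlleleCountPanel, signatures: SignatureSet
) -> FeatureMatrix:
    """Two features (reference and alternative read counts) per signature SNV.

    ``signatures.selected_mask`` must align with ``panel`` (i.e. the filtered
    panel the signatures were selected from).  Features with zero counts in
    every sample are dropped.
    """
    mask = np.asarray(signatures.selected_mask, dtype=bool)
    if mask.size != panel.n_sites:
        raise ValueError("signature mask does not align with the panel's sites")
    if not mask.any():
        raise EmptySignatureSetError(
            "no signature SNVs selected; relax the selection thresholds "
            "(lower sd_multiplier or min_site_depth)"
        )
    sub = panel.subset_sites(mask)
    ids = [
        f"{k.species_id}:{k.contig_id}:{k.position}:{allele}"
        for k in (sub.site_key(i) for i in range(sub.n_sites))
        for allele in (k.ref_allele, k.alt_allele)
    ]
    # interleave ref/alt rows per site
    sink = np.empty(2 * sub.n_sites, dtype=np.int64)
    sink[0::2], sink[1::2] = sub.sink_ref, sub.sink_alt
    src = np.empty((sub.n_sources, 2 * sub.n_sites), dtype=np.int64)
    src[:, 0::2], src[:, 1::2] = sub.source_ref.T, sub.source_alt.T
    sites = [
        f"{k.species_id}:{k.contig_id}:{k.position}"
        for k in (sub.site_key(i) for i in range(sub.n_sites))
        for _ in range(2)
    ]
    groups = [s.split(":", 1)[0] for s in sites]
    keep = (sink > 0) | (src > 0).any(axis=0)
    return FeatureMatrix(
        feature_ids=[i for i, k in zip(ids, keep) if k],
        sink_counts=sink[keep],
        source_counts=src[:, keep],
        source_names=list(sub.source_names),
        sink_name=sub.sink_name or "sink",
        feature_sites=[s for s, k in zip(sites, keep) if k],
        feature_groups=[g for g, k in zip(groups, keep) if k],
    )


def build_species_features(
    species_abundance: dict[str, dict[str, float]],
    sink_name: str,
    source_names: list[str],
    total_reads: int = 10_000,
) -> FeatureMatrix:
    """Species pseudo-count features from relative abundances.

    Abundances are scaled to ``total_reads`` and rounded; only species present
    in the sink are used.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    sink_ab = species_abundance[sink_name]
    species = sorted(sp for sp, a in sink_ab.items() if a > 0)
    if not species:
        raise ValueError(f"sink {sink_name!r} has no species with non-zero abundance")
    sink = np.array([round(sink_ab[sp] * total_reads) for sp in species], dtype=np.int64)
    src = np.array(
        [
            [round(species_abundance[s].get(sp, 0.0) * total_reads) for sp in species]
            for s in source_names
        ],
        dtype=np.int64,
    )
    keep = (sink > 0) | (src > 0).any(axis=0)
    return FeatureMatrix(
        feature_ids=[sp for sp, k in zip(species, keep) if k],
        sink_counts=sink[keep],
        source_counts=src[:, keep],
        source_names=list(source_names),
        sink_name=sink_name,
    )


# ------------------------------------------------------------------------ EM
def _rarefy(features: FeatureMatrix, rng: np.random.Generator) -> FeatureMatrix:
    totals = [features.sink_counts.sum()] + list(features.source_counts.sum(axis=1))
    depth = int(min(t for t in totals if t > 0))

    def sub(counts: np.ndarray) -> np.ndarray:
        total = counts.sum()
        if total <= depth:
            return counts
        return rng.multivariate_hypergeometric(counts, depth)

    sink = sub(features.sink_counts)
    src = np.vstack([sub(row) for row in features.source_counts])
    keep = (sink > 0) | (src > 0).any(axis=0)
    return FeatureMatrix(
        feature_ids=[i for i, k in zip(features.feature_ids, keep) if k],
        sink_counts=sink[keep],
        source_counts=src[:, keep],
        source_names=features.source_names,
        sink_name=features.sink_name,
    )


def _joint_loglik(x, y, alpha, gamma) -> float:
    mix = np.maximum(alpha @ gamma, 1e-300)
    nz = x > 0
    sink_term = float(np.sum(x[nz] * np.log(mix[nz])))
    gk = gamma[: y.shape[0]]
    src_nz = y > 0
    source_term = float(np.sum(y[src_nz] * np.log(np.maximum(gk[src_nz], 1e-300))))
    return sink_term + source_term


def _run_em(
    x: np.ndarray,
    y: np.ndarray,
    alpha0: np.ndarray,
    gamma0: np.ndarray,
    config: EMConfig,
    update_gamma: bool = True,
    freeze_unknown: bool = False,
) -> FeastModelState:
    """EM over (alpha, gamma).  gamma0 may have J rows (no unknown) or J+1."""
    alpha, gamma = alpha0.copy(), gamma0.copy()
    J = y.shape[0]
    has_unknown = gamma.shape[0] == J + 1
    N = x.sum()
    ll = _joint_loglik(x, y, alpha, gamma)
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        mix = alpha @ gamma  # (F,)
        with np.errstate(invalid="ignore", divide="ignore"):
            resp = alpha[:, None] * gamma / mix[None, :]
        resp[:, mix <= 0] = 0.0
        z = resp * x[None, :]
        assigned = z.sum(axis=1)
        alpha = assigned / N if N > 0 else np.full(gamma.shape[0], 1.0 / gamma.shape[0])
        if update_gamma:
            rows = [y + z[:J]]
            if has_unknown:
                unknown_row = gamma[J] * z[J].sum() if freeze_unknown else z[J]
                rows.append(unknown_row[None, :])
            new_gamma = np.vstack(rows)
            row_sums = new_gamma.sum(axis=1, keepdims=True)
            flat = row_sums[:, 0] <= 0
            new_gamma[flat] = gamma[flat]  # keep previous distribution for empty rows
            new_gamma[~flat] /= row_sums[~flat]
            gamma = new_gamma
        new_ll = _joint_loglik(x, y, alpha, gamma)
        if new_ll < ll - 1e-8 * max(1.0, abs(ll)):
            raise RuntimeError(
                f"EM log-likelihood decreased at iteration {it}: {ll} -> {new_ll}"
            )
        done = abs(new_ll - ll) <= config.tol * max(1.0, abs(ll))
        ll = new_ll
        if done:
            converged = True
            break
    return FeastModelState(alpha=alpha, gamma=gamma, loglik=ll, n_iter=it, converged=converged)


def _unknown_seed(
    x: np.ndarray, y: np.ndarray, config: EMConfig
) -> tuple[np.ndarray, np.ndarray, FeastModelState]:
    """Known-source-only fit plus the residual seed for the unknown's gamma.

    The unknown component makes the full mixture model degenerate: a free
    distribution fitted from the sink alone can always reproduce the sink
    exactly, so the global optimum is "all unknown" and a densely initialised
    unknown steadily absorbs sampling noise.  The estimator therefore first
    fits the known sources alone (a non-degenerate problem: contributions
    only, plug-in feature profiles, restricted to features where some known
    source has counts) and seeds the unknown with the *positive residual* of
    the sink over that fit, soft-thresholded at half a binomial standard
    error per feature.  Zeros in the seed are fixed points of the EM update
    for the unknown row, so the unknown can only ever claim features the
    known sources genuinely fail to explain.
    """
    J, F = y.shape
    N = x.sum()
    known_support = y.sum(axis=0) > 0
    xs = x[known_support]
    ys = y[:, known_support]
    gamma0 = np.empty((J, int(known_support.sum())))
    for j in range(J):
        tot = ys[j].sum()
        gamma0[j] = ys[j] / tot if tot > 0 else np.full(ys.shape[1], 1.0 / ys.shape[1])
    known_state = _run_em(
        xs, ys, np.full(J, 1.0 / J), gamma0, config, update_gamma=False
    )
    fitted = np.zeros(F)
    fitted[known_support] = (known_state.alpha @ known_state.gamma) * (
        xs.sum() / N if N > 0 else 0.0
    )
    resid = x / N - fitted if N > 0 else np.zeros(F)
    noise_sd = np.sqrt(fitted * N + 1.0) / max(N, 1.0)
    seed = np.maximum(resid - 0.5 * noise_sd, 0.0)
    # Under a no-unknown null the soft-thresholded residual still collects
    # mass: per feature, max(Z - 1/2, 0) in units of the noise SD has mean
    # E[max(Z - 1/2, 0)] = phi(1/2) - (1/2)(1 - Phi(1/2)) ~ 0.1978 and
    # SD ~ 0.4128.  An unknown component is introduced only when the seed
    # total is significantly (2 null SDs) above the null mean; the null mean
    # is then subtracted so pure noise contributes nothing in expectation.
    sd_known = noise_sd[known_support]
    null_mean = 0.1978 * float(sd_known.sum())
    null_sd = 0.4128 * float(np.sqrt((sd_known**2).sum()))
    total = float(seed.sum())
    if total <= null_mean + 2.0 * null_sd:
        seed[:] = 0.0
    else:
        seed *= 1.0 - null_mean / total
    gamma_known = np.zeros((J, F))
    gamma_known[:, known_support] = known_state.gamma
    return seed, gamma_known, known_state


def _extend_unknown_profile(
    x: np.ndarray,
    seed: np.ndarray,
    state: FeastModelState,
    features: FeatureMatrix,
) -> np.ndarray | None:
    """Species-level extension of the unknown's profile.

    The sparse residual seed credits the unknown only for reads on alleles no
    known source carries, yet a source contributing at a site of a species
    contributes at the same rate at all of that species' sites.  The unknown's
    local mixing share at a site with seed support is observable as its
    E-step read share of that site; the per-species share is estimated
    robustly as the 0.75 quantile over those sites (misfit-driven seed sites
    sit below the private-allele cluster, so the upper quartile lands on it)
    and extrapolated over the species' whole sink profile.  Returns the
    extended (unnormalised) profile, or None when there is no site structure
    to extrapolate over.
    """
    if features.feature_sites is None or features.feature_groups is None:
        return None
    J = len(features.source_names)
    mix = np.maximum(state.alpha @ state.gamma, 1e-300)
    z_u = state.alpha[J] * state.gamma[J] / mix * x
    sites = np.asarray(features.feature_sites)
    groups = np.asarray(features.feature_groups)
    seeded_sites = set(sites[seed > 0])
    extended = np.zeros_like(x)
    for group in np.unique(groups):
        in_group = groups == group
        lam_per_site = []
        for site in np.unique(sites[in_group]):
            in_site = sites == site
            if site not in seeded_sites:
                continue
            depth = x[in_site].sum()
            if depth > 0:
                lam_per_site.append(z_u[in_site].sum() / depth)
        if not lam_per_site:
            continue
        lam = min(float(np.quantile(lam_per_site, 0.75)), 1.0)
        extended[in_group] = lam * x[in_group]
    return extended if extended.sum() > 0 else None


def estimate_contributions(
    features: FeatureMatrix, config: EMConfig | None = None
) -> tuple[SourceContributionEstimate, FeastModelState]:
    """Estimate the contribution simplex (J known sources + unknown) for a sink.

    Staged estimation: the known sources are fitted alone; the unknown
    source's feature distribution is seeded from the noise-thresholded
    positive residual of that fit (see :func:`_unknown_seed`); the full
    (J+1)-component EM runs from a uniform contribution vector; and, when the
    features carry site/species structure, the unknown's profile is extended
    by its per-species local share (see :func:`_extend_unknown_profile`) and
    the EM is run once more from the extended start.  Optional random
    restarts redraw the starting contributions; the state with the best final
    log-likelihood within each stage is returned.  The returned alpha sums to
    1 within 1e-8; non-convergence within ``max_iter`` is flagged.
    """
    config = config or EMConfig()
    rng = np.random.default_rng(config.seed)
    if config.rarefy:
        features = _rarefy(features, rng)
    x = features.sink_counts.astype(float)
    y = features.source_counts.astype(float)
    J, F = y.shape

    seed, gamma_known, known_state = _unknown_seed(x, y, config)
    if seed.sum() <= 0:
        # nothing the known sources cannot explain: unknown contribution 0
        alpha = np.concatenate([known_state.alpha, [0.0]])
        gamma = np.vstack([gamma_known, np.zeros((1, F))])
        best = FeastModelState(
            alpha=alpha,
            gamma=gamma,
            loglik=known_state.loglik,
            n_iter=known_state.n_iter,
            converged=known_state.converged,
        )
    else:
        gamma0 = np.vstack([gamma_known, (seed / seed.sum())[None, :]])
        best = None
        for r in range(max(1, config.n_restarts)):
            a0 = (
                np.full(J + 1, 1.0 / (J + 1))
                if r == 0
                else rng.dirichlet(np.ones(J + 1))
            )
            state = _run_em(x, y, a0, gamma0.copy(), config)
            if best is None or state.loglik > best.loglik:
                best = state
        extended = _extend_unknown_profile(x, seed, best, features)
        if extended is not None and x.sum() > 0:
            # total unknown share implied by the per-species local shares;
            # known sources keep their relative proportions from the EM fit
            alpha_u = min(float(extended.sum() / x.sum()), 1.0)
            alpha_u = max(alpha_u, float(best.alpha[J]))  # never below the EM's direct claim
            known = best.alpha[:J]
            known_total = known.sum()
            if known_total > 0:
                known = known / known_total * (1.0 - alpha_u)
            best.alpha = np.concatenate([known, [alpha_u]])
            best.gamma[J] = extended / extended.sum()
    assert best is not None
    alpha = best.alpha / best.alpha.sum()  # exact renormalisation
    best.alpha = alpha
    contributions = {
        name: float(alpha[j]) for j, name in enumerate(features.source_names)
    }
    contributions[UNKNOWN] = float(alpha[J])
    return SourceContributionEstimate(features.sink_name, contributions), best
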