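"""End-to-end benchmark: four estimators on simulated transmission truth.

Each replicate simulates one sink from known mixing proportions and runs:

* SNV tracking — signature-SNV selection followed by EM on allele counts.
* species tracking — EM on species pseudo-counts.
* popANI fraction — per known source, the fraction of the sink's species
  called "same strain" (popANI >= 99.999%).
* marker-allele fraction — per known source, the fraction of species with
  >= 5% private-marker sharing between sink and source.

The EM estimators are compared with the full truth (known sources plus
unknown); the two binarised strain-sharing baselines only produce per-known-
source numbers, so their metrics are computed over known-source pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .baselines import compute_popani, find_marker_alleles, marker_sharing_calls, shared_species_fraction
from .em import EMConfig, EmptySignatureSetError, build_snv_features, build_species_features, estimate_contributions
from .evaluate import EvaluationMetrics, evaluate_estimates
from .scoring import FilterConfig, compute_signatures
from .simulate import SimulationConfig, SyntheticTruth, sample_mixture_proportions, simulate_experiment

__all__ = ["BenchmarkConfig", "BenchmarkReport", "run_benchmark", "run_replicate"]

ESTIMATORS = ("snv_feast", "species_feast", "popani_fraction", "marker_fraction")


@dataclass
class BenchmarkConfig:
    n_replicates: int = 20
    n_sources_range: tuple[int, int] = (3, 10)  # total contributing, incl. unknown
    transmission_modes: tuple[str, ...] = ("high", "low")
    seed: int = 0
    n_background: int = 2
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    em_config: EMConfig = field(default_factory=EMConfig)
    base_sim: SimulationConfig = field(default_factory=SimulationConfig)


@dataclass
class BenchmarkReport:
    results: pd.DataFrame  # replicate, estimator, sink, source, truth, estimate
    metrics: dict[str, EvaluationMetrics]
    failures: list[str] = field(default_factory=list)

    def truth_pairs(self, estimator: str) -> dict[tuple[str, str], float]:
        sub = self.results[self.results["estimator"] == estimator]
        return {(r.sink, r.source): r.truth for r in sub.itertuples()}


def _sim_config_for(base: SimulationConfig, cfg: BenchmarkConfig, rep: int, rng) -> SimulationConfig:
    lo, hi = cfg.n_sources_range
    n_sources = int(rng.integers(lo, hi + 1))
    mode = cfg.transmission_modes[rep % len(cfg.transmission_modes)]
    known, unknown = sample_mixture_proportions(n_sources - 1, rng)
    return replace(
        base,
        n_sources=n_sources,
        known_proportions=known,
        unknown_proportion=unknown,
        transmission_mode=mode,
        n_background=cfg.n_background,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def run_replicate(
    sim_config: SimulationConfig,
    filter_config: FilterConfig | None = None,
    em_config: EMConfig | None = None,
    estimators: tuple[str, ...] = ESTIMATORS,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Run the selected estimators on one simulated sink.

    Returns a tidy frame with one row per (estimator, source) — sources are
    the known sources plus, for the EM estimators, "unknown" — and the truth
    manifest.
    """
    filter_config = filter_config or FilterConfig()
    em_config = em_config or EMConfig()
    panel, truth, latent = simulate_experiment(sim_config)
    known = sim_config.known_sources
    sink = sim_config.sink_name
    truth_known = {s: truth.proportions[s] for s in known}
    truth_full = truth.estimation_truth()
    est_panel = panel.select_sources(known)  # background samples are not sources
    rows: list[dict] = []

    def add(estimator: str, estimates: dict[str, float], truth_map: dict[str, float]):
        for source, value in estimates.items():
            rows.append(
                {
                    "estimator": estimator,
                    "sink": sink,
                    "source": source,
                    "truth": truth_map[source],
                    "estimate": value,
                }
            )

    if "snv_feast" in estimators:
        filtered, signatures, _ = compute_signatures(est_panel, filter_config)
        features = build_snv_features(filtered, signatures)
        est, _ = estimate_contributions(features, em_config)
        add("snv_feast", est.contributions, truth_full)

    if "species_feast" in estimators:
        features = build_species_features(panel.species_abundance, sink, known)
        est, _ = estimate_contributions(features, em_config)
        add("species_feast", est.contributions, truth_full)

    if "popani_fraction" in estimators:
        for source in known:
            results = compute_popani(est_panel, sink, source)
            frac = shared_species_fraction(results) if results else 0.0
            add("popani_fraction", {source: frac}, truth_known)

    if "marker_fraction" in estimators:
        for source in known:
            background = [s for s in panel.source_names if s != source]
            reports = find_marker_alleles(panel, sink, source, background)
            summary = marker_sharing_calls(reports)
            frac = summary.fraction_species_shared
            add("marker_fraction", {source: 0.0 if frac is None else frac}, truth_known)

    return pd.DataFrame(rows), truth


def run_benchmark(config: BenchmarkConfig | None = None) -> BenchmarkReport:
    """Run all estimators over seeded replicates and pool the metrics.

    Replicates alternate transmission modes and draw the number of sources
    and the mixing proportions from the study ranges.  A failing replicate is
    recorded and skipped; the harness continues.
    """
    config = config or BenchmarkConfig()
    rng = np.random.default_rng(config.seed)
    frames: list[pd.DataFrame] = []
    failures: list[str] = []
    for rep in range(config.n_replicates):
        sim_config = _sim_config_for(config.base_sim, config, rep, rng)
        try:
            df, _ = run_replicate(sim_config, config.filter_config, config.em_config)
        except (EmptySignatureSetError, ValueError, RuntimeError) as exc:
            failures.append(f"replicate {rep}: {type(exc).__name__}: {exc}")
            continue
        df.insert(0, "replicate", rep)
        # sinks share a name across replicates; qualify for pooled evaluation
        df["sink"] = f"rep{rep:03d}:{sim_config.sink_name}"
        frames.append(df)
    results = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["replicate", "estimator", "sink", "source", "truth", "estimate"])
    )
    metrics: dict[str, EvaluationMetrics] = {}
    for estimator in results["estimator"].unique():
        sub = results[results["estimator"] == estimator]
        truth = {(r.sink, r.source): r.truth for r in sub.itertuples()}
        est = sub.rename(columns={"estimate": "proportion"})[["sink", "source", "proportion"]]
        metrics[estimator] = evaluate_estimates(est, truth)
    return BenchmarkReport(results=results, metrics=metrics, failures=failures)
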