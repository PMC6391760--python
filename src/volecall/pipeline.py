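"""End-to-end study reproduction: simulate -> measure -> analyze -> report.

Runs the whole design on synthetic data: generate per-group call populations
(118 Tien Shan / 108 hybrid / 78 bank calls by default, allocated across 10 /
4 / 5 animals), synthesise and measure every call, then produce the full
statistical report — group summaries, ANOVA and nonparametric comparisons,
the parent-species discriminant analysis with cross-validation and the
permutation chance level, chi-squared proportion comparisons, and the
Mahalanobis placement of every individual relative to the parent centroids.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .acoustics import measure
from .io import measurements_to_frame, write_wav
from .profiles import default_profiles, sample_call_specs, specs_to_frame
from .stats import (DEFAULT_FEATURES, DEFAULT_SEED, classify,
                    compare_proportions_chi2, fit_dfa, individual_means,
                    intermediacy_summary, kruskal_wallis_median,
                    mahalanobis_placement, one_way_anova, randomization_null,
                    split_half_cv)
from .synth import DEFAULT_SAMPLING_RATE_HZ, synthesize

log = logging.getLogger("volecall")

GROUP_ORDER = ("tien_shan", "hybrid", "bank")
PARENT_GROUPS = ("tien_shan", "bank")
ANOVA_PARAMETERS = ("duration_s", "f0max_hz", "mod_range_hz", "q50_hz",
                    "entropy")


@dataclass(frozen=True)
class RunConfig:
    """Validated study configuration (defaults follow the reference design)."""

    n_calls: dict[str, int] = field(default_factory=lambda: {
        "tien_shan": 118, "hybrid": 108, "bank": 78})
    n_individuals: dict[str, int] = field(default_factory=lambda: {
        "tien_shan": 10, "hybrid": 4, "bank": 5})
    calls_per_animal: int | None = None
    sampling_rate_hz: int = DEFAULT_SAMPLING_RATE_HZ
    fft_size: int = 512
    overlap: float = 0.875
    features: tuple[str, ...] = DEFAULT_FEATURES
    n_randomization: int = 100
    seed: int = DEFAULT_SEED
    write_wavs: bool = False


_DEFAULTS = RunConfig()
_KNOWN_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


def validate_config(raw: dict) -> RunConfig:
    """Build a fully-populated, range-checked RunConfig from a flat mapping."""
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = {**dataclasses.asdict(_DEFAULTS), **raw}
    cfg = RunConfig(**{k: (tuple(v) if k == "features" else v)
                       for k, v in merged.items()})
    for g, n in cfg.n_calls.items():
        if g not in GROUP_ORDER:
            raise ValueError(f"n_calls: unknown group {g!r}")
        if n < 1:
            raise ValueError(f"n_calls.{g}: must be >= 1, got {n}")
    for g, n in cfg.n_individuals.items():
        if g not in GROUP_ORDER:
            raise ValueError(f"n_individuals: unknown group {g!r}")
        if n < 1:
            raise ValueError(f"n_individuals.{g}: must be >= 1, got {n}")
    if cfg.calls_per_animal is not None and not 10 <= cfg.calls_per_animal <= 20:
        raise ValueError("calls_per_animal: allowed range is [10, 20] "
                         f"(got {cfg.calls_per_animal})")
    if not 0.0 <= cfg.overlap < 1.0:
        raise ValueError(f"overlap: must lie in [0, 1), got {cfg.overlap}")
    if cfg.fft_size < 16:
        raise ValueError("fft_size: must be >= 16")
    if cfg.sampling_rate_hz < 4000:
        raise ValueError("sampling_rate_hz: must be >= 4000")
    if cfg.n_randomization < 2:
        raise ValueError("n_randomization: must be >= 2")
    return cfg


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _allocate_individuals(group: str, n_calls: int, n_animals: int) -> list[str]:
    """Spread calls as evenly as possible across a group's animals."""
    base, extra = divmod(n_calls, n_animals)
    ids = []
    for a in range(n_animals):
        ids.extend([f"{group}_{a + 1:02d}"] * (base + (1 if a < extra else 0)))
    return ids


def simulate_calls(cfg: RunConfig, out_dir: Path | None = None
                   ) -> tuple[pd.DataFrame, list]:
    """Draw call specs for every group; returns (ground-truth table, specs).

    Per-call synthesis seeds are derived from the master seed; with
    ``write_wavs`` the rendered calls are saved as one WAV per call.
    """
    profiles = default_profiles()
    rng = np.random.default_rng(cfg.seed)
    frames, all_specs = [], []
    for group in GROUP_ORDER:
        n = cfg.n_calls.get(group, 0)
        if cfg.calls_per_animal is not None:
            n = cfg.calls_per_animal * cfg.n_individuals[group]
        if n == 0:
            continue
        specs = sample_call_specs(profiles[group], n, rng)
        gt = specs_to_frame(specs, group=group)
        gt["individual_id"] = _allocate_individuals(
            group, n, cfg.n_individuals[group])
        gt["synth_seed"] = rng.integers(0, 2 ** 31, size=n)
        frames.append(gt)
        all_specs.extend(specs)
    truth = pd.concat(frames, ignore_index=True)
    truth["call_id"] = [f"{g}_{i:04d}" for i, g in enumerate(truth["group"])]
    if out_dir is not None and cfg.write_wavs:
        wav_dir = Path(out_dir) / "wav"
        wav_dir.mkdir(parents=True, exist_ok=True)
        for spec, (_, row) in zip(all_specs, truth.iterrows()):
            w = synthesize(spec, cfg.sampling_rate_hz, int(row["synth_seed"]))
            write_wav(wav_dir / f"{row['call_id']}.wav", w)
    return truth, all_specs


def measure_calls(truth: pd.DataFrame, specs: list, cfg: RunConfig
                  ) -> pd.DataFrame:
    """Synthesise and measure every call in the ground-truth table."""
    measurements = []
    for spec, seed in zip(specs, truth["synth_seed"]):
        w = synthesize(spec, cfg.sampling_rate_hz, int(seed))
        measurements.append(measure(w, fft_size=cfg.fft_size,
                                    overlap=cfg.overlap))
    return measurements_to_frame(
        measurements,
        call_ids=list(truth["call_id"]),
        individual_ids=list(truth["individual_id"]),
        groups=list(truth["group"]))


def _group_summaries(df: pd.DataFrame) -> dict:
    out = {}
    params = ("duration_s", "peak_hz", "q25_hz", "q50_hz", "q75_hz",
              "entropy", "f0max_hz", "mod_range_hz")
    for group, sub in df.groupby("group"):
        entry = {"n_calls": int(len(sub))}
        for p in params:
            vals = sub[p].dropna()
            entry[p] = {"mean": float(vals.mean()),
                        "se": float(vals.std(ddof=1) / np.sqrt(len(vals)))
                        if len(vals) > 1 else None,
                        "n": int(len(vals))}
        entry["structure_counts"] = {
            k: int(v) for k, v in sub["structure"].value_counts().items()}
        out[group] = entry
    return out


def analyze_measurements(df: pd.DataFrame, cfg: RunConfig) -> dict:
    """The full statistics chain on a measurements table."""
    names = [g for g in GROUP_ORDER if g in set(df["group"])]
    report: dict = {"group_summaries": _group_summaries(df)}

    anova = {}
    for p in ANOVA_PARAMETERS:
        samples = [df.loc[df["group"] == g, p].dropna().to_numpy()
                   for g in names]
        if any(len(s) < 2 for s in samples):
            continue
        r = one_way_anova(samples, names=names)
        anova[p] = {"F": r.F, "df": [r.df_between, r.df_within], "p": r.p,
                    "tukey_reject": {f"{a}|{b}": v
                                     for (a, b), v in r.posthoc.items()}}
    report["anova"] = anova

    kw = kruskal_wallis_median(
        [df.loc[df["group"] == g, "peak_hz"].to_numpy() for g in names],
        names=names)
    report["peak_frequency_nonparametric"] = {
        "H": kw.H, "p_kruskal": kw.p_kruskal,
        "median_chi2": kw.median_chi2, "p_median": kw.p_median,
        "grand_median_hz": kw.grand_median,
        "pairwise": {f"{a}|{b}": {"z": z, "p_bonferroni": p}
                     for (a, b), (z, p) in kw.pairwise_z.items()},
        "group_medians_hz": {g: float(df.loc[df["group"] == g,
                                             "peak_hz"].median())
                             for g in names},
    }

    parents = df[df["group"].isin(PARENT_GROUPS)]
    model = fit_dfa(parents, groups=PARENT_GROUPS, features=cfg.features)
    resub = classify(model, parents)
    cv = split_half_cv(parents, groups=PARENT_GROUPS, features=cfg.features,
                       seed=cfg.seed)
    null = randomization_null(parents, groups=PARENT_GROUPS,
                              features=cfg.features,
                              n_reps=cfg.n_randomization, seed=cfg.seed)
    n_parents = int(len(parents))
    chi_cv = compare_proportions_chi2(resub.percent_correct, n_parents,
                                      cv, n_parents - n_parents // 2)
    chi_null = compare_proportions_chi2(resub.percent_correct, n_parents,
                                        null.mean_percent, n_parents)
    report["parent_dfa"] = {
        "features": list(cfg.features),
        "resubstitution_percent": resub.percent_correct,
        "confusion": {str(i): {str(c): int(v) for c, v in row.items()}
                      for i, row in resub.confusion.iterrows()},
        "wilks_lambda": resub.wilks_lambda,
        "wilks_partial": resub.wilks_partial,
        "crossvalidation_percent": cv,
        "randomization_null": {"mean_percent": null.mean_percent,
                               "se_percent": null.se_percent,
                               "n_reps": null.n_reps},
        "chi2_resub_vs_crossval": {"chi2": chi_cv[0], "p": chi_cv[1]},
        "chi2_resub_vs_null": {"chi2": chi_null[0], "p": chi_null[1]},
    }

    means = individual_means(df, features=cfg.features)
    pl = mahalanobis_placement(parents, means, PARENT_GROUPS,
                               features=cfg.features)
    inter = intermediacy_summary(pl)
    report["mahalanobis"] = {
        "parent_groups": list(PARENT_GROUPS),
        "individuals": pl.table.to_dict(orient="records"),
        "hybrids": inter.per_hybrid.to_dict(orient="records"),
        "n_intermediate": inter.n_intermediate,
        "nearer_counts": inter.nearer_counts,
        "majority_nearer": inter.majority_nearer,
    }
    report["_placement"] = pl   # non-serialised, for plotting
    return report


def plot_placement(report: dict, path: Path) -> None:
    """Scatter of per-individual D2 to each parent centroid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pl = report["_placement"]
    fig, ax = plt.subplots(figsize=(5, 5))
    colors = {"tien_shan": "tab:blue", "bank": "tab:green",
              "hybrid": "tab:red"}
    for group, sub in pl.table.groupby("group"):
        ax.scatter(sub["d2_a"], sub["d2_b"], label=group,
                   color=colors.get(group, "gray"), s=40)
    ax.set_xlabel(f"squared Mahalanobis distance to {pl.parent_groups[0]}")
    ax.set_ylabel(f"squared Mahalanobis distance to {pl.parent_groups[1]}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_study(cfg: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full study; optionally write all artefacts to *out_dir*.

    Returns the report dict; with an output directory it also writes
    ``ground_truth.csv``, ``measurements.csv``, ``report.json`` and the
    placement scatter ``mahalanobis.png``.  Bit-reproducible for a fixed
    config and seed.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    log.info("simulate: seed=%d groups=%s", cfg.seed, dict(cfg.n_calls))
    truth, specs = simulate_calls(cfg, out_dir=out)
    log.info("simulate: %d calls drawn", len(truth))
    df = measure_calls(truth, specs, cfg)
    log.info("measure: %d calls measured", len(df))
    report = analyze_measurements(df, cfg)
    log.info("analyze: parent DFA %.1f%% correct",
             report["parent_dfa"]["resubstitution_percent"])
    report["provenance"] = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "config_hash": config_hash(cfg),
    }
    if out is not None:
        truth.to_csv(out / "ground_truth.csv", index=False)
        df.to_csv(out / "measurements.csv", index=False)
        plot_placement(report, out / "mahalanobis.png")
        serial = {k: v for k, v in report.items() if not k.startswith("_")}
        (out / "report.json").write_text(
            json.dumps(_jsonable(serial), sort_keys=True, indent=2))
    return report
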