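"""Desk-scale end-to-end experiments.

Each ``run_*`` function builds (or receives) a stimulus corpus, trains the
sparse-coding hierarchy where needed, and reports the layer-wise modulation
and sparseness analyses, the receptive-field control, the lambda sweep, the
statistics regression, and the CM-vs-SM statistic correlations.  All
cross-condition significance testing routes through :mod:`texsig.stats`.

Reports are plain dictionaries (JSON/CSV-serializable) embedding the
configuration hash and every seed, so a rerun with the same config is
reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics, shmax, stats, texstats
from .stimuli import StimulusCorpus, build_corpus

__all__ = [
    "ExperimentConfig",
    "run_baseline",
    "run_lambda_sweep",
    "run_rf_control",
    "run_stat_regression",
    "run_cm_sm_stat_correlation",
    "run_train_on_sm",
]

LAMBDA_SWEEP_DEFAULT = (0.01, 0.02, 0.05, 0.1, 0.25, 0.35, 0.45)


@dataclass
class ExperimentConfig:
    """Shared configuration of the desk-scale experiments."""

    experiment: str = "baseline"
    n_families: int = 10
    n_per_family: int = 12
    image_size: int = 64
    n_big: int = 3
    filters: tuple[int, ...] = (24, 32, 48)
    kernels: tuple[int, ...] = (7, 5, 3)
    strides: tuple[int, ...] = (2, 1, 1)
    lambdas: tuple[float, ...] | None = None
    n_patches_per_image: int = 150
    n_train_per_family: int = 8
    n_train_iters: int = 15
    n_models: int = 10
    n_perm: int = 2000
    rst_n_sample: int = 100
    rst_reps: int = 500
    seed: int = 0
    out_dir: str | None = None
    # lambda sweep specifics
    sweep_layer: int = 2
    lambda_grid: tuple[float, ...] = LAMBDA_SWEEP_DEFAULT
    # rf control specifics
    split_lower_big: int = 0
    split_fraction: float = 0.5

    def spec(self) -> shmax.NetworkSpec:
        return shmax.desk_spec(n_big=self.n_big, m=self.filters,
                               lam=self.lambdas, kernels=self.kernels,
                               strides=self.strides)

    def hash(self) -> str:
        doc = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def _report_header(cfg: ExperimentConfig) -> dict:
    return {"experiment": cfg.experiment, "config": asdict(cfg),
            "config_hash": cfg.hash(), "seed": cfg.seed}


def _seeds(cfg: ExperimentConfig, n: int, salt: int = 0) -> list[int]:
    root = np.random.SeedSequence([cfg.seed, salt])
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(n)]


def _training_images(cfg: ExperimentConfig) -> list:
    """Structured textures from the same families but disjoint image draws.

    The models are trained on images the evaluation pairs are not part of
    (the stand-in for training on an independent natural-image corpus);
    training on the test pairs themselves lets small top layers memorize
    individual stimuli.
    """
    train_seed = _seeds(cfg, 1, salt=991)[0]
    tc = build_corpus(cfg.n_families, cfg.n_train_per_family,
                      cfg.image_size, seed=train_seed, family_seed=cfg.seed)
    return [p.cm.pixels for p in tc.pairs]


def _train_and_extract(cfg: ExperimentConfig, corpus: StimulusCorpus,
                       train_images, seed: int,
                       random_weights: bool = False) -> list:
    """Train one model and return per-big-layer response matrices."""
    model = shmax.ShmaxModel(cfg.spec(),
                             n_patches_per_image=cfg.n_patches_per_image,
                             n_iters=cfg.n_train_iters)
    res = model.fit(train_images, seed=seed)
    if random_weights:
        res = res.with_random_weights(seed=seed + 1)
    return metrics.extract_all_big_layers(res, corpus), res


def run_baseline(cfg: ExperimentConfig,
                 corpus: StimulusCorpus | None = None,
                 random_weights: bool = False) -> dict:
    """Layer-wise modulation analysis of a trained (or random-weight) model.

    Reports per-big-layer PMI, the percentage of significantly positively
    modulated units (per-unit randomization test), RST comparisons between
    consecutive layers and against zero, per-family PMIs, and the
    sparseness-modulation scatter.
    """
    corpus = corpus or build_corpus(cfg.n_families, cfg.n_per_family,
                                    cfg.image_size, seed=cfg.seed)
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    train_images = _training_images(cfg)
    seed = _seeds(cfg, 1, salt=1)[0]
    Rs, res = _train_and_extract(cfg, corpus, train_images, seed,
                                 random_weights=random_weights)
    report = _report_header(cfg)
    report["random_weights"] = random_weights
    layers = []
    prev_idx = None
    for b, R in enumerate(Rs):
        mod = metrics.compute_modulation(R)
        sp = metrics.unit_sparseness_table(R)
        dead = np.isnan(mod.indices).all()
        with np.errstate(invalid="ignore"):
            entry = {
                "big_layer": b + 1,
                "pmi": mod.overall_pmi,
                "n_units": R.n_units,
                "n_excluded": mod.n_excluded,
                "mean_lifetime_sparseness": float(np.nanmean(sp["lifetime"]))
                if not np.isnan(sp["lifetime"]).all() else float("nan"),
                "population_sparseness": metrics.population_sparseness(R),
                "scatter": {"sparseness": sp["lifetime"].tolist(),
                            "modulation": mod.indices.tolist()},
            }
        entry["family_pmi"] = mod.family_pmi
        if dead:
            # no unit responded to any stimulus: no preference to test
            entry["pct_significant"] = float("nan")
            entry["rst_p_vs_zero"] = float("nan")
        else:
            rt = stats.unit_randomization_test(R, n_perm=cfg.n_perm,
                                               seed=seed + 7 + b)
            entry["pct_significant"] = 100.0 * rt.fraction_significant
            rst_zero = stats.random_sampling_ttest(
                mod.indices, "zero", n_sample=cfg.rst_n_sample,
                reps=cfg.rst_reps, seed=seed + 11 + b)
            entry["rst_p_vs_zero"] = rst_zero.p_value
        if prev_idx is not None:
            if dead or np.isnan(prev_idx).all():
                entry["rst_p_vs_below"] = float("nan")
            else:
                rst = stats.random_sampling_ttest(
                    mod.indices, prev_idx, n_sample=cfg.rst_n_sample,
                    reps=cfg.rst_reps, seed=seed + 13 + b)
                entry["rst_p_vs_below"] = rst.p_value
        layers.append(entry)
        prev_idx = mod.indices
    report["layers"] = layers
    report["training_seed"] = seed
    _maybe_write(cfg, report)
    return report


def run_lambda_sweep(cfg: ExperimentConfig,
                     corpus: StimulusCorpus | None = None) -> dict:
    """Sparseness-modulation curve of one big layer across the lambda grid.

    For each lambda, ``n_models`` models are trained from different seeds
    with the swept big layer's lambda replaced; the report carries the mean
    lifetime sparseness and PMI of that layer per lambda, a quadratic fit
    of PMI on sparseness, and a monotonicity summary.
    """
    if not 0 <= cfg.sweep_layer < cfg.n_big:
        raise ValueError(f"sweep layer {cfg.sweep_layer} out of range")
    corpus = corpus or build_corpus(cfg.n_families, cfg.n_per_family,
                                    cfg.image_size, seed=cfg.seed)
    train_images = _training_images(cfg)
    base_lam = tuple(0.15 if b < 2 else 0.1 for b in range(cfg.n_big))
    rows = []
    for lam in cfg.lambda_grid:
        lams = tuple(lam if b == cfg.sweep_layer else base_lam[b]
                     for b in range(cfg.n_big))
        sub = _replace(cfg, lambdas=lams)
        for seed in _seeds(cfg, cfg.n_models, salt=hash(lam) % 1000):
            Rs, _ = _train_and_extract(sub, corpus, train_images, seed)
            R = Rs[cfg.sweep_layer]
            mod = metrics.compute_modulation(R)
            sp = metrics.unit_sparseness_table(R)
            rows.append({"lam": lam, "seed": seed,
                         "pmi": mod.overall_pmi,
                         "lifetime_sparseness": float(np.nanmean(sp["lifetime"])),
                         "nonfiring": float(np.nanmean(sp["nonfiring"]))})
    df = pd.DataFrame(rows)
    summary = df.groupby("lam", as_index=False).mean(numeric_only=True)
    report = _report_header(cfg)
    report["per_model"] = rows
    report["per_lambda"] = summary.to_dict("records")
    if summary.shape[0] >= 3:
        coef = np.polyfit(summary["lifetime_sparseness"], summary["pmi"], 2)
        report["quadratic_fit"] = coef.tolist()
    else:
        report["quadratic_fit"] = None
        report["note"] = "fewer than 3 lambda values; quadratic fit skipped"
    s = summary.sort_values("lam")
    report["nonfiring_monotone_in_lambda"] = bool(
        np.all(np.diff(s["nonfiring"]) >= -0.02))
    _maybe_write(cfg, report)
    return report


def run_rf_control(cfg: ExperimentConfig,
                   corpus: StimulusCorpus | None = None) -> dict:
    """Two-path receptive-field control.

    Splits two consecutive big layers, asserts rf(a) == rf(b) > rf(c)
    before any statistics, trains ``n_models`` seeds, and reports per-set
    PMIs with a one-tailed paired t-test (a vs b) and a two-tailed paired
    t-test (b vs c) across models.
    """
    base = cfg.spec()
    split_spec = shmax.build_two_path(base, cfg.split_lower_big,
                                      cfg.split_lower_big + 1,
                                      split=cfg.split_fraction)
    rf = shmax.rf_size_sets(split_spec)
    assert rf["a"] == rf["b"] > rf["c"], f"rf arithmetic violated: {rf}"
    corpus = corpus or build_corpus(cfg.n_families, cfg.n_per_family,
                                    cfg.image_size, seed=cfg.seed)
    train_images = _training_images(cfg)
    rows = []
    for seed in _seeds(cfg, cfg.n_models, salt=3):
        model = shmax.ShmaxModel(split_spec,
                                 n_patches_per_image=cfg.n_patches_per_image,
                                 n_iters=cfg.n_train_iters)
        res = model.fit(train_images, seed=seed)
        sets = metrics.extract_set_responses(res, corpus)
        row = {"seed": seed}
        for name, R in sets.items():
            row[f"pmi_{name}"] = metrics.compute_modulation(R).overall_pmi
        rows.append(row)
    df = pd.DataFrame(rows)
    from scipy import stats as sps
    t_ab = sps.ttest_rel(df["pmi_a"], df["pmi_b"], alternative="greater")
    t_bc = sps.ttest_rel(df["pmi_b"], df["pmi_c"], alternative="two-sided")
    report = _report_header(cfg)
    report.update({
        "rf_sizes": rf,
        "per_model": rows,
        "mean_pmi": {k: float(df[f"pmi_{k}"].mean()) for k in ("a", "b", "c")},
        "sd_pmi": {k: float(df[f"pmi_{k}"].std(ddof=1)) for k in ("a", "b", "c")},
        "p_a_gt_b_paired_one_tailed": float(t_ab.pvalue),
        "p_b_vs_c_paired_two_tailed": float(t_bc.pvalue),
    })
    _maybe_write(cfg, report)
    return report


def run_stat_regression(cfg: ExperimentConfig,
                        corpus: StimulusCorpus | None = None,
                        bank: texstats.FilterBank | None = None) -> dict:
    """Regress per-pair top-layer modulation on grouped image statistics.

    The design comes from the structured (CM-role) images via signed-sqrt,
    z-scoring and groupwise PCA; group contributions to the full-model R^2
    are decomposed by averaging-over-orderings and sum to 100%.
    """
    corpus = corpus or build_corpus(cfg.n_families, cfg.n_per_family,
                                    cfg.image_size, seed=cfg.seed)
    if len(corpus) < 2:
        raise ValueError("need at least 2 pairs")
    train_images = _training_images(cfg)
    seed = _seeds(cfg, 1, salt=4)[0]
    Rs, _ = _train_and_extract(cfg, corpus, train_images, seed)
    target = metrics.per_pair_pmi(Rs[-1])
    bank = bank or texstats.FilterBank(
        n_scales=3, base_wavelength=3.0)
    # cap per-group components so the design stays estimable at desk-scale
    # pair counts; at reference scale (1000 pairs) the cap is inactive
    cap = max(2, len(corpus) // 12)
    design = texstats.build_design(corpus.cm_images(), bank,
                                   max_components=cap)
    fit = texstats.fit_pmi_regression(design, target)
    contrib = fit.lmg()
    report = _report_header(cfg)
    report.update({
        "r_squared": fit.rsquared,
        "lmg_percent": contrib,
        "lmg_sum": float(sum(contrib.values())),
        "variance_retained": design.variance_retained,
        "scatter": {"measured": target.tolist(),
                    "predicted": fit.fittedvalues.tolist()},
    })
    _maybe_write(cfg, report)
    return report


def run_cm_sm_stat_correlation(cfg: ExperimentConfig,
                               corpus: StimulusCorpus | None = None,
                               bank: texstats.FilterBank | None = None
                               ) -> dict:
    """Per-group correlation of statistics between paired CM and SM images.

    On a phase-scramble corpus the position groups are expected to
    correlate more strongly than the scale groups; a violation of that
    ordering is flagged in the report.
    """
    corpus = corpus or build_corpus(cfg.n_families, cfg.n_per_family,
                                    cfg.image_size, seed=cfg.seed)
    bank = bank or texstats.FilterBank(n_scales=3, base_wavelength=3.0)
    res = texstats.group_correlation_cm_sm(corpus, bank)
    table = {g: res[g]["r"] for g in texstats.GROUP_NAMES if g in res}
    pos = np.nanmean([table.get("lin_position", np.nan),
                      table.get("en_position", np.nan)])
    sca = np.nanmean([table.get("lin_scale", np.nan),
                      table.get("en_scale", np.nan)])
    report = _report_header(cfg)
    report.update({
        "group_r": table,
        "position_exceeds_scale": bool(pos > sca),
    })
    if not report["position_exceeds_scale"]:
        report["flag"] = ("position-group correlation did not exceed "
                          "scale-group correlation")
    _maybe_write(cfg, report)
    return report


def run_train_on_sm(cfg: ExperimentConfig,
                    corpus: StimulusCorpus | None = None,
                    baseline_report: dict | None = None) -> dict:
    """Baseline analysis for a model trained on the phase-scrambled images.

    Reports the same per-layer table as :func:`run_baseline` plus a
    side-by-side PMI comparison with a structured-trained baseline (which
    must be supplied or is run first).
    """
    corpus = corpus or build_corpus(cfg.n_families, cfg.n_per_family,
                                    cfg.image_size, seed=cfg.seed)
    if baseline_report is None:
        baseline_report = run_baseline(_replace(cfg, out_dir=None), corpus)
    if "layers" not in baseline_report:
        raise ValueError("baseline report missing layer table")
    train_images = [p.sm.pixels for p in corpus.pairs]
    seed = _seeds(cfg, 1, salt=5)[0]
    Rs, _ = _train_and_extract(cfg, corpus, train_images, seed)
    rows = []
    for b, R in enumerate(Rs):
        mod = metrics.compute_modulation(R)
        rows.append({
            "big_layer": b + 1,
            "pmi_sm_trained": mod.overall_pmi,
            "pmi_structured_trained": baseline_report["layers"][b]["pmi"],
        })
    report = _report_header(cfg)
    report["comparison"] = rows
    report["training_seed"] = seed
    _maybe_write(cfg, report)
    return report


# ---------------------------------------------------------------------------

def _replace(cfg: ExperimentConfig, **kw) -> ExperimentConfig:
    doc = asdict(cfg)
    doc.update(kw)
    for key in ("filters", "kernels", "strides", "lambda_grid"):
        if doc[key] is not None:
            doc[key] = tuple(doc[key])
    if doc["lambdas"] is not None:
        doc["lambdas"] = tuple(doc["lambdas"])
    return ExperimentConfig(**doc)


def _maybe_write(cfg: ExperimentConfig, report: dict) -> None:
    if not cfg.out_dir:
        return
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / f"{cfg.experiment}_{cfg.hash()}.json"
    path.write_text(json.dumps(report, indent=1, default=_json_default))
    flat = report.get("layers") or report.get("per_lambda") \
        or report.get("comparison") or report.get("per_model")
    if flat:
        pd.json_normalize(flat).to_csv(path.with_suffix(".csv"), index=False)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return str(obj)


def load_config(path: str | Path) -> ExperimentConfig:
    """Read an ExperimentConfig from a YAML (or JSON) document."""
    import yaml

    doc = yaml.safe_load(Path(path).read_text())
    return _replace(ExperimentConfig(), **doc)
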