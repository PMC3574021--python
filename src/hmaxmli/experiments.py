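"""Experiment orchestration: training/testing protocols and summaries.

The protocol mirrors a two-stage psychophysics design.  Each *run* trains a
fresh network — new cross-fin (XF) training images, newly sampled S2
prototypes and a newly trained SVM — and then tests it on fresh images of
the requested conditions, so between-run variability is honest run-level
independence and error bars are standard errors of the mean across runs.

Defaults follow the study protocol: 450 XF training images (225 per
category), 150 test images per category, 1000 S2 prototypes, 10 runs.

Three canned experiments are provided:

* :func:`size_sweep` — control (LR) accuracy as a function of network size.
* :func:`illusion_experiment` — LR vs ML accuracy per category, with the
  paired and two-sample t-tests used to compare them.
* :func:`psychometric_experiment` — proportion-LONG curves over exact length
  differences for the control and for ML at fixed fin angles, with logistic
  fits and PSEs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import stimuli
from .stimuli import LONG, SHORT, SweepSpec
from .hmax import (HmaxConfig, GaborBank, PrototypeBank, make_gabor_bank,
                   compute_c1, c2_from_c1, sample_prototypes)
from .decision import TrainedClassifier, train_classifier, predict
from .psychometrics import (PsychometricCurve, FitError, fit_sigmoid,
                            estimate_pse)

log = logging.getLogger("hmaxmli")


@dataclass
class RunConfig:
    """Protocol parameters; the defaults reproduce the study conditions."""

    n_train_per_category: int = 225      # 450 training images in total
    n_test_per_category: int = 150
    n_prototypes: int = 1000             # network size (S2 units)
    n_runs: int = 10
    master_seed: int = 0
    svm_c: float = 1e4
    sweep_diffs: tuple = tuple(range(-60, 61, 10))
    images_per_diff: int = 50
    sweep_angles: tuple = (20.0, 40.0, 60.0)
    hmax: HmaxConfig = field(default_factory=HmaxConfig)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class TrainedNetwork:
    """One trained instance: Gabor bank, S2 prototypes and decision layer."""

    gabor: GaborBank
    prototypes: PrototypeBank
    classifier: TrainedClassifier
    config: RunConfig

    def encode(self, images) -> np.ndarray:
        rows = [c2_from_c1(compute_c1(im.pixels, self.gabor), self.prototypes)
                for im in images]
        return np.asarray(rows)

    def classify(self, images) -> pd.DataFrame:
        labels, values = predict(self.classifier, self.encode(images))
        return pd.DataFrame({
            "label": [im.label for im in images],
            "predicted": labels,
            "decision_value": values,
            "top_length": [im.spec.top_length for im in images],
            "bottom_length": [im.spec.bottom_length for im in images],
        })


@dataclass
class ExperimentResult:
    """Per-run accuracies (%) for one condition, with mean and SEM."""

    condition: str
    per_run_overall: np.ndarray
    per_run_by_category: dict
    decisions: list                      # one classify() frame per run

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_run_overall))

    @property
    def sem(self) -> float:
        if len(self.per_run_overall) < 2:
            return float("nan")
        return float(stats.sem(self.per_run_overall))

    def category_mean(self, category: str) -> float:
        return float(np.mean(self.per_run_by_category[category]))

    def category_sem(self, category: str) -> float:
        vals = self.per_run_by_category[category]
        return float(stats.sem(vals)) if len(vals) > 1 else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "condition": self.condition,
            "run": np.arange(len(self.per_run_overall)),
            "overall": self.per_run_overall,
            LONG: self.per_run_by_category[LONG],
            SHORT: self.per_run_by_category[SHORT],
        })


# ---------------------------------------------------------------------------
# training and single runs

def train_network(config: RunConfig, seed) -> TrainedNetwork:
    """Train one fresh network: XF images → prototypes → C2 → linear SVM."""
    rng = np.random.default_rng(seed)
    gabor = make_gabor_bank(config.hmax)
    train_images = stimuli.generate_dataset("XF", config.n_train_per_category,
                                            rng)
    c1_sets = [compute_c1(im.pixels, gabor) for im in train_images]
    protos = sample_prototypes(c1_sets, config.n_prototypes, rng=rng,
                               config=config.hmax)
    pbank = PrototypeBank(protos, config.hmax)
    c2 = np.asarray([c2_from_c1(c1, pbank) for c1 in c1_sets])
    clf = train_classifier(c2, [im.label for im in train_images], C=config.svm_c)
    log.info("trained network: %d prototypes, config %s",
             config.n_prototypes, config.config_hash())
    return TrainedNetwork(gabor=gabor, prototypes=pbank, classifier=clf,
                          config=config)


def _accuracies(frame: pd.DataFrame) -> tuple:
    correct = frame["label"] == frame["predicted"]
    overall = 100.0 * correct.mean()
    by_cat = {cat: 100.0 * correct[frame["label"] == cat].mean()
              for cat in (LONG, SHORT)}
    return overall, by_cat


def run_once(config: RunConfig, condition_styles=("LR",), seed=None):
    """One full train/test cycle; returns per-condition accuracy and decisions."""
    seed = config.master_seed if seed is None else seed
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    train_seed, *test_seeds = ss.spawn(1 + len(condition_styles))
    network = train_network(config, train_seed)
    out = {}
    for style, tseed in zip(condition_styles, test_seeds):
        test = stimuli.generate_dataset(style, config.n_test_per_category,
                                        np.random.default_rng(tseed))
        frame = network.classify(test)
        overall, by_cat = _accuracies(frame)
        out[style] = {"overall": overall, "by_category": by_cat,
                      "decisions": frame}
    return out, network


def _multi_run(config: RunConfig, condition_styles, keep_networks=False):
    """n_runs independent train/test cycles over the given test styles."""
    ss = np.random.SeedSequence(config.master_seed)
    run_seeds = ss.spawn(config.n_runs)
    acc = {s: [] for s in condition_styles}
    cat = {s: {LONG: [], SHORT: []} for s in condition_styles}
    frames = {s: [] for s in condition_styles}
    networks = []
    for r, rseed in enumerate(run_seeds):
        result, network = run_once(config, condition_styles, rseed)
        for s in condition_styles:
            acc[s].append(result[s]["overall"])
            for c in (LONG, SHORT):
                cat[s][c].append(result[s]["by_category"][c])
            frames[s].append(result[s]["decisions"])
        if keep_networks:
            networks.append(network)
        log.info("run %d/%d: %s", r + 1, config.n_runs,
                 {s: f"{acc[s][-1]:.1f}%" for s in condition_styles})
    results = {s: ExperimentResult(
        condition=s,
        per_run_overall=np.asarray(acc[s]),
        per_run_by_category={c: np.asarray(cat[s][c]) for c in (LONG, SHORT)},
        decisions=frames[s]) for s in condition_styles}
    return (results, networks) if keep_networks else results


# ---------------------------------------------------------------------------
# Experiment I: accuracy vs network size

def size_sweep(config: RunConfig, sizes) -> dict:
    """Control (LR) accuracy for each network size in ``sizes``."""
    out = {}
    for d in sizes:
        if d < 1:
            raise ValueError("network size must be >= 1")
        cfg = RunConfig(**{**asdict(config), "n_prototypes": int(d),
                           "hmax": config.hmax})
        out[int(d)] = _multi_run(cfg, ("LR",))["LR"]
    return out


# ---------------------------------------------------------------------------
# Experiment II: control vs illusion accuracy

def illusion_experiment(config: RunConfig) -> dict:
    """LR vs ML accuracies per category plus the reported t-tests.

    Comparisons: a paired two-tailed t-test between the control LONG and
    SHORT accuracies (within the same runs), and two-sample equal-variance
    t-tests between LR and ML within each category.
    """
    results = _multi_run(config, ("LR", "ML"))
    lr, ml = results["LR"], results["ML"]
    t_cat = stats.ttest_rel(lr.per_run_by_category[LONG],
                            lr.per_run_by_category[SHORT])
    tests = {"control_long_vs_short_paired": {"t": float(t_cat.statistic),
                                              "p": float(t_cat.pvalue)}}
    for c in (LONG, SHORT):
        t = stats.ttest_ind(lr.per_run_by_category[c],
                            ml.per_run_by_category[c], equal_var=True)
        tests[f"{c.lower()}_lr_vs_ml"] = {"t": float(t.statistic),
                                          "p": float(t.pvalue)}
    return {"LR": lr, "ML": ml, "tests": tests}


# ---------------------------------------------------------------------------
# Experiment III: psychometric curves and PSE per fin angle

def _sweep_curve(network: TrainedNetwork, sweep: SweepSpec) -> PsychometricCurve:
    images = stimuli.generate_sweep(sweep)
    frame = network.classify(images)
    diffs = np.asarray(sweep.diffs, dtype=float)
    n_long = np.zeros(len(diffs), dtype=int)
    n_total = np.zeros(len(diffs), dtype=int)
    signed = frame["top_length"].to_numpy() - frame["bottom_length"].to_numpy()
    is_long = (frame["predicted"] == LONG).to_numpy()
    for i, d in enumerate(diffs):
        sel = signed == d
        n_total[i] = int(sel.sum())
        n_long[i] = int(is_long[sel].sum())
    return PsychometricCurve(diffs=diffs, n_long=n_long, n_total=n_total)


def psychometric_experiment(config: RunConfig, angles=None,
                            include_control: bool = True) -> dict:
    """Psychometric curves for the control and each ML fin angle.

    One network is trained per run; every condition is tested on that same
    network.  Per-run curves are fitted individually (the per-run PSEs give
    the mean ± SEM) and also pooled across runs for a single aggregate fit.
    Returns ``{condition: {"per_run_pse", "pse_mean", "pse_sem", "curve",
    "fit", "pse", "per_run_curves"}}`` with conditions named ``"control"``
    and ``"ML<angle>"``.
    """
    angles = config.sweep_angles if angles is None else tuple(angles)
    conditions = ([("control", "LR", None)] if include_control else []) + \
        [(f"ML{a:g}", "ML", float(a)) for a in angles]
    ss = np.random.SeedSequence(config.master_seed)
    run_seeds = ss.spawn(config.n_runs)
    curves = {name: [] for name, _, _ in conditions}
    for r, rseed in enumerate(run_seeds):
        train_seed, sweep_ss = rseed.spawn(2)
        network = train_network(config, train_seed)
        for (name, style, angle), cseed in zip(conditions,
                                               sweep_ss.spawn(len(conditions))):
            sweep = SweepSpec(style=style, fin_angle=angle,
                              diffs=tuple(config.sweep_diffs),
                              images_per_diff=config.images_per_diff,
                              seed=cseed)
            curves[name].append(_sweep_curve(network, sweep))
        log.info("psychometric run %d/%d done", r + 1, config.n_runs)
    out = {}
    for name, _, _ in conditions:
        per_run = curves[name]
        per_run_pse = []
        for c in per_run:
            try:
                per_run_pse.append(estimate_pse(fit_sigmoid(c)))
            except FitError as exc:
                log.warning("%s: per-run fit failed (%s)", name, exc)
                per_run_pse.append(np.nan)
        pooled = PsychometricCurve(
            diffs=per_run[0].diffs,
            n_long=np.sum([c.n_long for c in per_run], axis=0),
            n_total=np.sum([c.n_total for c in per_run], axis=0))
        fit = fit_sigmoid(pooled)
        try:
            pooled_pse = estimate_pse(fit)
        except FitError as exc:
            log.warning("%s: pooled PSE not identified (%s)", name, exc)
            pooled_pse = float("nan")
        per_run_pse = np.asarray(per_run_pse)
        ok = np.isfinite(per_run_pse)
        out[name] = {
            "per_run_curves": per_run,
            "per_run_pse": per_run_pse,
            "pse_mean": float(np.mean(per_run_pse[ok])) if ok.any() else np.nan,
            "pse_sem": (float(stats.sem(per_run_pse[ok]))
                        if ok.sum() > 1 else float("nan")),
            "curve": pooled,
            "fit": fit,
            "pse": pooled_pse,
        }
    return out


# ---------------------------------------------------------------------------
# network serialisation

def save_network(path, network: TrainedNetwork) -> None:
    """Serialise prototypes, classifier and config to a single NPZ archive."""
    protos = network.prototypes.prototypes
    patches = np.concatenate([p.patch.reshape(-1) for p in protos])
    sizes = np.array([p.size for p in protos])
    sources = np.array([p.source for p in protos])
    np.savez(path,
             patches=patches.astype(np.float32), sizes=sizes, sources=sources,
             clf_weights=network.classifier.weights,
             clf_bias=network.classifier.bias,
             clf_c=network.classifier.c_reg,
             config=np.str_(json.dumps(asdict(network.config))),
             prototype_key=np.str_(network.prototypes.content_hash()))


def load_network(path) -> TrainedNetwork:
    from .hmax import Prototype
    with np.load(path) as f:
        raw = json.loads(str(f["config"]))
        raw["hmax"] = HmaxConfig(**{**raw["hmax"],
                                    "prototype_sizes": tuple(raw["hmax"]["prototype_sizes"])})
        raw["sweep_diffs"] = tuple(raw["sweep_diffs"])
        raw["sweep_angles"] = tuple(raw["sweep_angles"])
        config = RunConfig(**raw)
        n_orient = config.hmax.n_orientations
        protos, off = [], 0
        for size, src in zip(f["sizes"], f["sources"]):
            count = n_orient * int(size) ** 2
            patch = f["patches"][off:off + count].reshape(n_orient, size, size)
            protos.append(Prototype(patch=patch, size=int(size),
                                    source=tuple(int(x) for x in src)))
            off += count
        clf = TrainedClassifier(weights=f["clf_weights"],
                                bias=float(f["clf_bias"]),
                                n_features=len(protos),
                                c_reg=float(f["clf_c"]))
    return TrainedNetwork(gabor=make_gabor_bank(config.hmax),
                          prototypes=PrototypeBank(protos, config.hmax),
                          classifier=clf, config=config)


# ---------------------------------------------------------------------------
# result output

def save_results(outdir, results: dict, config: RunConfig) -> None:
    """Write per-run accuracy CSVs and a JSON summary for a result dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = {"config_hash": config.config_hash(), "config": asdict(config)}
    frames = []
    for key, val in results.items():
        if isinstance(val, ExperimentResult):
            frames.append(val.to_frame())
            summary[key] = {
                "mean": val.mean, "sem": val.sem,
                LONG: val.category_mean(LONG), SHORT: val.category_mean(SHORT)}
        elif isinstance(val, dict) and "curve" in val:
            curve = val["curve"]
            pd.DataFrame({"diff": curve.diffs, "n_long": curve.n_long,
                          "n_total": curve.n_total,
                          "proportion_long": curve.proportion_long}
                         ).to_csv(outdir / f"curve_{key}.csv", index=False)
            summary[key] = {"pse": val["pse"], "pse_mean": val["pse_mean"],
                            "pse_sem": val["pse_sem"]}
        else:
            summary[key] = val
    if frames:
        pd.concat(frames).to_csv(outdir / "per_run_accuracy.csv", index=False)
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, default=str))
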