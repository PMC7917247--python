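"""Study orchestration: splits, view extraction, the 15-cell study grid,
metrics, and the training-set-size ablation.

The study grid crosses three analysis views (first-derivative mean spectra,
synthesized RGB frames, trimmed reflectance cubes) with five classifiers
(LR, SVM, NN, DT, CNN). Samples are split 3:1:1 into train/validation/test
within every acquisition session; the three views share one split so the
same leaves occupy the same sets everywhere.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .baselines import METHODS, SearchSpace, boa_tune
from .models import TrainConfig, build_cnn3d, build_resnet18, \
    extract_pooled_features, predict, train_model
from .preprocess import ReflectanceHSI, calibrate_reflectance, first_derivative, \
    mean_roi_spectrum, resize_sample, sg_smooth_3d, standardize_sets, \
    synthesize_rgb, trim_bands
from .synthetic import SyntheticDataset, WavelengthGrid

logger = logging.getLogger(__name__)

SPLITS = ("train", "val", "test")
VIEWS = ("spectra", "rgb", "hsi")


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    """Assignment of sample ids to train/validation/test."""

    table: pd.DataFrame  # columns: id, class, session, split

    def ids(self, split: str) -> list:
        return self.table.loc[self.table["split"] == split, "id"].tolist()

    def counts(self) -> pd.DataFrame:
        """Per-split class counts (rows: class, columns: split)."""
        return self.table.pivot_table(index="class", columns="split", values="id",
                                      aggfunc="count", fill_value=0)[list(SPLITS)]


def _largest_remainder(n: int, ratio: tuple) -> tuple:
    """Split n into len(ratio) integers proportional to ratio; leftovers go
    to the largest fractional remainders, earlier ratio entries win ties."""
    total = sum(ratio)
    exact = [n * r / total for r in ratio]
    floors = [int(np.floor(e)) for e in exact]
    rem = n - sum(floors)
    order = sorted(range(len(ratio)), key=lambda i: (-(exact[i] - floors[i]), i))
    for i in order[:rem]:
        floors[i] += 1
    return tuple(floors)


def stratified_split(manifest: pd.DataFrame, ratio: tuple = (3, 1, 1),
                     seed: int = 0, quotas: dict | None = None) -> SplitSpec:
    """Per-session, per-class shuffled 3:1:1 assignment.

    ``quotas`` optionally maps ``(session, class)`` to explicit
    ``(train, val, test)`` cell sizes (the default synthetic study pins these
    to reproduce its reference bookkeeping); otherwise cells round by the
    largest-remainder rule with the training share favoured on ties.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (session, label), group in manifest.groupby(["session", "class"], sort=True):
        n = len(group)
        if n < sum(ratio):
            logger.warning("split cell session=%s class=%s has only %d samples",
                           session, label, n)
        if quotas is not None and (session, label) in quotas:
            t, v, u = quotas[(session, label)]
            if t + v + u != n:
                raise ValueError(f"quotas for cell ({session}, {label}) sum to "
                                 f"{t + v + u}, but the cell has {n} samples")
        else:
            t, v, u = _largest_remainder(n, ratio)
        ids = group["id"].to_numpy()[rng.permutation(n)]
        for sid, split in zip(ids, ["train"] * t + ["val"] * v + ["test"] * u):
            rows.append({"id": sid, "class": label, "session": session,
                         "split": split})
    table = pd.DataFrame(rows)
    order = {i: k for k, i in enumerate(manifest["id"])}
    table = table.sort_values("id", key=lambda s: s.map(order)).reset_index(drop=True)
    return SplitSpec(table=table)


def confusion_and_accuracy(predictions, labels):
    """2x2 confusion matrix (rows = true 0/1, cols = predicted) and
    accuracy = 100 * trace / total in percent."""
    pred = np.asarray(predictions)
    true = np.asarray(labels)
    if pred.size == 0 or pred.shape != true.shape:
        raise ValueError("predictions and labels must be equal-length and non-empty")
    cm = np.zeros((2, 2), dtype=int)
    for t, p in ((0, 0), (0, 1), (1, 0), (1, 1)):
        cm[t, p] = int(np.sum((true == t) & (pred == p)))
    return cm, float(100.0 * np.trace(cm) / cm.sum())


# ---------------------------------------------------------------------------
# presets and views
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyPreset:
    """Problem sizes of one run profile (frame sizes, schedules, trial counts)."""

    name: str
    gen_height: int
    gen_width: int
    resize_rgb: int
    resize_hsi: int
    epochs_spectra: int
    epochs_rgb: int
    epochs_hsi: int
    boa_iterations: int

    def epochs_for(self, view: str) -> int:
        return {"spectra": self.epochs_spectra, "rgb": self.epochs_rgb,
                "hsi": self.epochs_hsi}[view]


#: Desk-scale profile: small frames and short schedules for CPU runs.
DESK = StudyPreset("desk", gen_height=48, gen_width=64, resize_rgb=32,
                   resize_hsi=24, epochs_spectra=25, epochs_rgb=20,
                   epochs_hsi=12, boa_iterations=40)
#: Full-scale profile matching the reference study settings.
PAPER = StudyPreset("paper", gen_height=520, gen_width=696, resize_rgb=160,
                    resize_hsi=160, epochs_spectra=200, epochs_rgb=200,
                    epochs_hsi=200, boa_iterations=200)

PRESETS = {p.name: p for p in (DESK, PAPER)}


@dataclass
class StudyViews:
    """The three analysis views of one dataset plus shared bookkeeping."""

    spectra: np.ndarray          # (n, B) first-derivative mean spectra
    rgb: np.ndarray              # (n, 3, S, S)
    cubes: np.ndarray            # (n, B, S, S) trimmed reflectance
    labels: np.ndarray
    sessions: np.ndarray
    ids: list
    grid: WavelengthGrid         # trimmed grid
    manifest: pd.DataFrame
    split: SplitSpec | None = None
    secretion_masks: np.ndarray | None = None  # (n, S, S) bool, resized

    def split_indices(self) -> tuple:
        """(train, val, test) integer index arrays in manifest order."""
        if self.split is None:
            raise ValueError("views carry no split; call stratified_split first")
        pos = {sid: k for k, sid in enumerate(self.ids)}
        return tuple(np.array([pos[i] for i in self.split.ids(s)], dtype=int)
                     for s in SPLITS)


def extract_views(dataset: SyntheticDataset, preset: StudyPreset = DESK,
                  split_seed: int = 0, progress: bool = False) -> StudyViews:
    """Render every sample and derive the three views.

    Chain per sample: render raw -> reflectance calibration -> 5x5x5
    Savitzky-Golay smoothing -> (RGB from the full grid; trim to 461-988 nm
    for spectra and cubes) -> mean ROI spectrum + first derivative; RGB and
    cube spatially resized to the preset target.
    """
    n = len(dataset)
    spectra, rgbs, cubes, masks = [], [], [], []
    trimmed_grid = None
    for i in range(n):
        raw, scene = dataset.sample(i)
        refl = calibrate_reflectance(raw)
        smooth = ReflectanceHSI(sg_smooth_3d(refl.cube), refl.grid)
        rgb = synthesize_rgb(smooth, scene.leaf_mask)
        rgb = resize_sample(rgb, preset.resize_rgb)
        rgbs.append(np.moveaxis(rgb.pixels, -1, 0).astype(np.float32))
        trimmed = trim_bands(smooth)
        trimmed_grid = trimmed.grid
        mean_spec = mean_roi_spectrum(trimmed, scene.leaf_mask)
        spectra.append(first_derivative(mean_spec, trimmed.grid))
        cubes.append(resize_sample(trimmed.cube, preset.resize_hsi).astype(np.float32))
        mask = resize_sample(scene.secretion_mask[None].astype(float),
                             preset.resize_rgb)[0] > 0.5
        masks.append(mask)
        if progress and (i + 1) % 32 == 0:
            logger.info("extract_views: %d/%d samples", i + 1, n)
    manifest = dataset.manifest
    views = StudyViews(
        spectra=np.array(spectra), rgb=np.array(rgbs), cubes=np.array(cubes),
        labels=manifest["class"].to_numpy(), sessions=manifest["session"].to_numpy(),
        ids=manifest["id"].tolist(), grid=trimmed_grid, manifest=manifest,
        secretion_masks=np.array(masks),
    )
    views.split = stratified_split(manifest, seed=split_seed,
                                   quotas=dataset.config.split_quotas)
    return views


# ---------------------------------------------------------------------------
# the full study
# ---------------------------------------------------------------------------

@dataclass
class RunRecord:
    """Everything one study run produced."""

    seed: int
    preset: str
    stage_seeds: dict
    timings: dict
    results: pd.DataFrame        # one row per (view, method)
    predictions: pd.DataFrame    # id, view, method, split, true, predicted
    models: dict = field(default_factory=dict, repr=False)  # view -> TrainedModel

    def accuracy(self, view: str, method: str, split: str = "test") -> float:
        row = self.results[(self.results["view"] == view)
                           & (self.results["method"] == method)]
        return float(row[f"{split}_accuracy"].iloc[0])

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.results.to_csv(outdir / "results.csv", index=False)
        self.predictions.to_csv(outdir / "predictions.csv", index=False)


def _cells_from_predictions(pred_rows: list) -> dict:
    out = {}
    for split in SPLITS:
        rows = [r for r in pred_rows if r["split"] == split]
        cm, acc = confusion_and_accuracy([r["predicted"] for r in rows],
                                         [r["true"] for r in rows])
        out[f"{split}_00"], out[f"{split}_01"] = int(cm[0, 0]), int(cm[0, 1])
        out[f"{split}_10"], out[f"{split}_11"] = int(cm[1, 0]), int(cm[1, 1])
        out[f"{split}_accuracy"] = round(acc, 2)
    return out


def _stage_seeds(seed: int) -> dict:
    rng = np.random.default_rng(seed)
    names = ["split", "cnn_spectra", "cnn_rgb", "cnn_hsi",
             "boa_spectra", "boa_rgb", "boa_hsi", "ablation"]
    return {name: int(rng.integers(0, 2 ** 31)) for name in names}


def run_full_study(views: StudyViews, preset: StudyPreset = DESK,
                   seed: int = 0, methods: tuple = METHODS + ("CNN",),
                   views_to_run: tuple = VIEWS) -> RunRecord:
    """Execute the study grid (3 views x {LR, SVM, NN, DT, CNN}).

    Per view, the CNN is trained first; for the image and cube views its
    global-pooling features then feed the conventional classifiers (the
    spectra view feeds them the standardized first-derivative spectra
    directly). All inputs are standardized with training-set statistics.
    """
    seeds = _stage_seeds(seed)
    tr, va, te = views.split_indices()
    y = views.labels
    idx_by_split = dict(zip(SPLITS, (tr, va, te)))
    results_rows, pred_rows, timings, models = [], [], {}, {}

    for view in views_to_run:
        t0 = time.time()
        cnn_seed = seeds[f"cnn_{view}"]
        cfg = TrainConfig(epochs=preset.epochs_for(view), seed=cnn_seed)
        if view == "spectra":
            X = views.spectra
            Xtr, Xva, Xte, _ = standardize_sets(X[tr], X[va], X[te])
            net = build_resnet18("1d", (1, X.shape[1]), seed=cnn_seed)
            shape = (1, X.shape[1])
        elif view == "rgb":
            X = views.rgb
            Xtr, Xva, Xte, _ = standardize_sets(X[tr], X[va], X[te])
            net = build_resnet18("2d", X.shape[1:], seed=cnn_seed)
            shape = X.shape[1:]
        else:
            X = views.cubes
            Xtr, Xva, Xte, _ = standardize_sets(X[tr], X[va], X[te])
            net = build_cnn3d(input_shape=X.shape[1:], seed=cnn_seed)
            shape = (1,) + X.shape[1:]
        sets = {s: a.reshape((len(a),) + shape).astype(np.float32)
                for s, a in zip(SPLITS, (Xtr, Xva, Xte))}
        trained = None
        if "CNN" in methods:
            trained = train_model(net, (sets["train"], y[tr]), (sets["val"], y[va]), cfg)
            models[view] = trained
            for split in SPLITS:
                labels, _ = predict(trained, sets[split])
                for k, j in enumerate(idx_by_split[split]):
                    pred_rows.append({"id": views.ids[j], "view": view,
                                      "method": "CNN", "split": split,
                                      "true": int(y[j]), "predicted": int(labels[k])})
                rows = [r for r in pred_rows if r["view"] == view
                        and r["method"] == "CNN"]
            results_rows.append({"view": view, "method": "CNN",
                                 **_cells_from_predictions(rows)})
        timings[f"cnn_{view}"] = time.time() - t0

        # feature table for the conventional classifiers
        if view == "spectra":
            feats = {s: sets[s].reshape(len(sets[s]), -1) for s in SPLITS}
        else:
            if trained is None:
                continue
            raw_feats = {s: extract_pooled_features(trained, sets[s]) for s in SPLITS}
            ftr, fva, fte, _ = standardize_sets(raw_feats["train"], raw_feats["val"],
                                                raw_feats["test"])
            feats = dict(zip(SPLITS, (ftr, fva, fte)))

        t0 = time.time()
        boa_rng = np.random.default_rng(seeds[f"boa_{view}"])
        for method in [m for m in methods if m != "CNN"]:
            space = SearchSpace(method=method, n_iterations=preset.boa_iterations)
            tuned = boa_tune(method, space, (feats["train"], y[tr]),
                             (feats["val"], y[va]),
                             seed=int(boa_rng.integers(0, 2 ** 31)))
            cell_rows = []
            for split in SPLITS:
                pred = tuned.estimator.predict(feats[split])
                for k, j in enumerate(idx_by_split[split]):
                    row = {"id": views.ids[j], "view": view, "method": method,
                           "split": split, "true": int(y[j]),
                           "predicted": int(pred[k])}
                    pred_rows.append(row)
                    cell_rows.append(row)
            results_rows.append({"view": view, "method": method,
                                 **_cells_from_predictions(cell_rows)})
        timings[f"baselines_{view}"] = time.time() - t0

    results = pd.DataFrame(results_rows)
    predictions = pd.DataFrame(pred_rows)
    return RunRecord(seed=seed, preset=preset.name, stage_seeds=seeds,
                     timings=timings, results=results, predictions=predictions,
                     models=models)


# ---------------------------------------------------------------------------
# training-set-size ablation
# ---------------------------------------------------------------------------

def training_size_ablation(views: StudyViews,
                           sizes: tuple = ((25, 27), (50, 52), (75, 78)),
                           preset: StudyPreset = DESK, seed: int = 0) -> pd.DataFrame:
    """Grow the training set (nested subsets, per-class counts as given)
    while validation and test sets stay fixed; 1-D CNN accuracy per size."""
    tr, va, te = views.split_indices()
    y = views.labels
    rng = np.random.default_rng(seed)
    pools = {c: tr[y[tr] == c][rng.permutation(int((y[tr] == c).sum()))]
             for c in (0, 1)}
    X = views.spectra
    rows = []
    val_ids = [views.ids[j] for j in va]
    test_ids = [views.ids[j] for j in te]
    for n_healthy, n_infected in sizes:
        if n_healthy > len(pools[0]) or n_infected > len(pools[1]):
            raise ValueError(f"requested size {(n_healthy, n_infected)} exceeds "
                             f"the training pool ({len(pools[0])}, {len(pools[1])})")
        sub = np.concatenate([pools[0][:n_healthy], pools[1][:n_infected]])
        Xtr, Xva, Xte, _ = standardize_sets(X[sub], X[va], X[te])
        shape = (1, X.shape[1])
        net = build_resnet18("1d", shape, seed=seed)
        cfg = TrainConfig(epochs=preset.epochs_spectra, seed=seed)
        trained = train_model(net, (Xtr.reshape((len(sub),) + shape), y[sub]),
                              (Xva.reshape((len(va),) + shape), y[va]), cfg)
        labels, _ = predict(trained, Xte.reshape((len(te),) + shape))
        _, acc = confusion_and_accuracy(labels, y[te])
        labels_v, _ = predict(trained, Xva.reshape((len(va),) + shape))
        _, acc_v = confusion_and_accuracy(labels_v, y[va])
        rows.append({"n_healthy": n_healthy, "n_infected": n_infected,
                     "val_accuracy": round(acc_v, 2),
                     "test_accuracy": round(acc, 2),
                     "val_ids": ";".join(val_ids), "test_ids": ";".join(test_ids)})
    return pd.DataFrame(rows)
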