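"""Gradient-saliency attribution for the trained classifiers.

For a sample ``D0`` of true class ``c`` the saliency weight is

    w = | dS_c / dD  at D0 |

with ``S_c`` the *pre-softmax* class score, computed by backpropagation; a
sample is *valid* for aggregation only when the model predicts its true
class. From ``w`` the package derives

* a spatial map ``M(i, j) = max_v w(i, j, v)`` (maximum over wavelengths),
* per-sample band profiles normalized to sum 1,
* the cumulative contribution ``C = sum_j M_j / || sum_j M_j ||_1`` over a
  sample set (band vectors ``w_j`` take the place of ``M_j`` for 1-D input),
* a per-band L1 contribution for cubes (sum of ``w`` over pixels and samples,
  L1-normalized),

plus the band-subset re-modelling check: retrain a network on a wavelength
interval only and compare test accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import Model, TrainConfig, TrainedModel, build_cnn3d, \
    build_resnet18, predict, train_model
from .preprocess import standardize_sets


@dataclass
class SaliencyResult:
    """Eq.-style gradient weights for one sample."""

    sample_id: str
    datum: np.ndarray          # D0, shaped like the model input (channel axis incl.)
    true_class: int
    score: float               # S_c at D0 (pre-softmax)
    w: np.ndarray              # |dS_c/dD|, same shape as datum
    valid: bool                # prediction matched the true class


@dataclass
class SpatialSaliencyMap:
    """Per-pixel maximum of w over the wavelength (channel) axis."""

    M: np.ndarray
    sample_id: str


@dataclass
class ContributionProfile:
    """L1-normalized cumulative contribution over a sample set."""

    values: np.ndarray
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        if np.any(self.values < 0):
            raise ValueError("contribution values must be non-negative")
        if not np.isclose(self.values.sum(), 1.0, atol=1e-8):
            raise ValueError("contribution profile must sum to 1")


def saliency_weights(model: Model | TrainedModel, sample: np.ndarray,
                     true_class: int, sample_id: str = "") -> SaliencyResult:
    """Backpropagate the true-class pre-softmax score to the input.

    ``sample`` must be preprocessed exactly like the training inputs and
    shaped like one model input. ``w`` is returned for every sample;
    ``valid`` is False when the prediction disagrees with the true class,
    and such samples are excluded from every aggregation below.
    """
    net = model.model if isinstance(model, TrainedModel) else model
    x = np.asarray(sample, dtype=float)
    if tuple(x.shape) != net.input_shape:
        raise ValueError(f"sample shape {x.shape} != model input {net.input_shape}")
    logits = net.forward(x[None], train=False)
    dlogits = np.zeros_like(logits)
    dlogits[0, true_class] = 1.0
    dx = net.backward(dlogits)[0]
    return SaliencyResult(sample_id=sample_id, datum=x, true_class=int(true_class),
                          score=float(logits[0, true_class]), w=np.abs(dx),
                          valid=bool(logits[0].argmax() == true_class))


def _squeezed(result: SaliencyResult) -> np.ndarray:
    return np.squeeze(result.w)


def spatial_map(result: SaliencyResult) -> SpatialSaliencyMap:
    """Per-pixel max of w over the wavelength/channel axis (cube or image)."""
    w = _squeezed(result)
    if w.ndim < 3:
        raise ValueError("spatial map needs a (bands, H, W) weight array")
    return SpatialSaliencyMap(M=w.max(axis=0), sample_id=result.sample_id)


def per_sample_normalize(result: SaliencyResult) -> np.ndarray:
    """Band vector w / sum(w) of one correctly predicted 1-D sample."""
    if not result.valid:
        raise ValueError("per-sample normalization requires a valid "
                         "(correctly predicted) sample")
    w = _squeezed(result)
    if w.ndim != 1:
        raise ValueError("per-sample normalization applies to 1-D weights")
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate all-zero attribution")
    return w / total


def _summand(result: SaliencyResult) -> np.ndarray:
    w = _squeezed(result)
    return w if w.ndim == 1 else w.max(axis=0)


def cumulative_contribution(results: list) -> ContributionProfile:
    """C = sum_j M_j / ||sum_j M_j||_1 over the valid samples (band vectors
    w_j for 1-D input, spatial maps M_j for cubes/images)."""
    valid = [r for r in results if r.valid]
    if not valid:
        raise ValueError("no valid (correctly predicted) samples to aggregate")
    total = np.sum([_summand(r) for r in valid], axis=0)
    norm = np.abs(total).sum()
    if norm <= 0:
        raise ValueError("degenerate all-zero aggregate")
    return ContributionProfile(values=total / norm,
                               sample_ids=[r.sample_id for r in valid])


def band_l1_contribution(results: list) -> np.ndarray:
    """Per-band total |gradient| over pixels and valid cube samples,
    L1-normalized to 1."""
    valid = [r for r in results if r.valid]
    if not valid:
        raise ValueError("no valid (correctly predicted) samples to aggregate")
    sums = []
    for r in valid:
        w = _squeezed(r)
        if w.ndim != 3:
            raise ValueError("band L1 contribution applies to cube weights")
        sums.append(w.sum(axis=(1, 2)))
    total = np.sum(sums, axis=0)
    return total / total.sum()


def band_subset_remodel(views, band_range_nm: tuple, view: str = "spectra",
                        train_config: TrainConfig | None = None,
                        seed: int = 0) -> float:
    """Restrict the chosen view to band centres inside the closed nm range,
    retrain the matching CNN from scratch and return its test accuracy (%).

    Used to confirm that wavelength ranges with high saliency contribution
    carry more class information than low-contribution ranges.
    """
    from .pipeline import StudyViews  # local import; pipeline does not import us
    if not isinstance(views, StudyViews):
        raise TypeError("views must be a StudyViews container")
    if view not in ("spectra", "hsi"):
        raise ValueError("band-subset re-modelling applies to 'spectra' or 'hsi'")
    lo, hi = band_range_nm
    keep = views.grid.indices_in(lo, hi)
    if keep.size == 0:
        raise ValueError(f"no band centres in [{lo}, {hi}] nm")
    cfg = train_config or TrainConfig(epochs=25, seed=seed)
    tr, va, te = views.split_indices()
    y = views.labels
    if view == "spectra":
        X = views.spectra[:, keep]
        Xtr, Xva, Xte, _ = standardize_sets(X[tr], X[va], X[te])
        shape = (1, keep.size)
        model = build_resnet18("1d", shape, seed=seed)
    else:
        X = views.cubes[:, keep]
        Xtr, Xva, Xte, _ = standardize_sets(X[tr], X[va], X[te])
        shape = (1,) + X.shape[1:]
        model = build_cnn3d(input_shape=X.shape[1:], seed=seed)
    Xtr = Xtr.reshape((len(tr),) + shape)
    Xva = Xva.reshape((len(va),) + shape)
    Xte = Xte.reshape((len(te),) + shape)
    trained = train_model(model, (Xtr, y[tr]), (Xva, y[va]), cfg)
    labels, _ = predict(trained, Xte)
    return float(100.0 * (labels == y[te]).mean())
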