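"""Synthetic Vis/NIR hyperspectral leaf scenes with known ground truth.

Emulates the statistical structure of a single-leaf cotton aphid-infection
imaging study: 128-band radiance cubes spanning 376-1044 nm, a 50%-gray
reference frame, vegetation-like reflectance with a green bump / red edge /
NIR plateau, and two classes where infection (i) depresses the NIR plateau
inside a configurable discriminative wavelength window and (ii) paints small
bright, spectrally flat honeydew-secretion patches inside the leaf.

Every scene is deterministic given the generator seed, so downstream models,
saliency attribution and split bookkeeping are testable without any
downloaded data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_utils import write_envi, write_mask_png

HEALTHY, INFECTED = 0, 1

#: Per-session sample counts for the default dataset: 125 healthy and 131
#: infected leaves over five acquisition sessions (totals chosen so that a
#: 3:1:1 split can reproduce the reference bookkeeping of 75/78, 26/25, 24/28).
DEFAULT_HEALTHY_PER_SESSION = (27, 26, 25, 24, 23)
DEFAULT_INFECTED_PER_SESSION = (27, 27, 27, 25, 25)

#: Default per-(session, class) split quotas (train, validation, test).
#: See docs/methods.md: no symmetric per-cell rounding rule yields the
#: reference pooled counts for both classes at once, so the default dataset
#: pins the cell quotas explicitly.
DEFAULT_SPLIT_QUOTAS = {
    (1, HEALTHY): (16, 6, 5),
    (2, HEALTHY): (16, 5, 5),
    (3, HEALTHY): (15, 5, 5),
    (4, HEALTHY): (14, 5, 5),
    (5, HEALTHY): (14, 5, 4),
    (1, INFECTED): (16, 5, 6),
    (2, INFECTED): (16, 5, 6),
    (3, INFECTED): (16, 5, 6),
    (4, INFECTED): (15, 5, 5),
    (5, INFECTED): (15, 5, 5),
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band centres in nanometres, shared by all cubes of a study."""

    centers: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "centers", c)
        if c.ndim != 1 or c.size < 1:
            raise ValueError("grid needs at least one band center")
        if not np.all(np.diff(c) > 0):
            raise ValueError("band centers must be strictly ascending")

    def __len__(self) -> int:
        return int(self.centers.size)

    @property
    def spacing(self) -> float:
        """Median centre-to-centre spacing in nm."""
        if self.centers.size < 2:
            raise ValueError("spacing is undefined for a single-band grid")
        return float(np.median(np.diff(self.centers)))

    def band_index(self, nm: float, *, max_offset: float | None = None) -> int:
        """Index of the band centre nearest ``nm``.

        Raises ``ValueError`` when the nearest centre is farther than
        ``max_offset`` (default: half a band spacing).
        """
        idx = int(np.argmin(np.abs(self.centers - nm)))
        tol = self.spacing / 2.0 if max_offset is None else max_offset
        if abs(self.centers[idx] - nm) > tol:
            raise ValueError(
                f"no band centre within {tol:.3f} nm of {nm} nm "
                f"(nearest: {self.centers[idx]:.2f} nm)")
        return idx

    def indices_in(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Indices of centres inside the closed interval [lo, hi] nm."""
        return np.flatnonzero((self.centers >= lo_nm) & (self.centers <= hi_nm))


def make_wavelength_grid(n_bands: int = 128, lo_nm: float = 376.0,
                         hi_nm: float = 1044.0) -> WavelengthGrid:
    """Uniform inclusive grid of ``n_bands`` centres from ``lo_nm`` to ``hi_nm``."""
    if n_bands < 2:
        raise ValueError("n_bands must be at least 2")
    if not lo_nm < hi_nm:
        raise ValueError("wavelength range must satisfy lo < hi")
    return WavelengthGrid(np.linspace(lo_nm, hi_nm, int(n_bands)))


@dataclass
class SceneTruth:
    """Ground truth for one synthetic leaf scene."""

    leaf_mask: np.ndarray
    vein_mask: np.ndarray
    edge_mask: np.ndarray
    secretion_mask: np.ndarray
    class_label: int
    session: int
    true_reflectance: np.ndarray  # (bands, H, W), unitless in [0, 1.2]

    def validate(self) -> None:
        if self.class_label not in (HEALTHY, INFECTED):
            raise ValueError("class_label must be 0 (healthy) or 1 (infected)")
        if np.any(self.vein_mask & ~self.leaf_mask):
            raise ValueError("vein mask must be contained in the leaf mask")
        if np.any(self.secretion_mask & ~self.leaf_mask):
            raise ValueError("secretion mask must be contained in the leaf mask")
        if self.class_label == HEALTHY and self.secretion_mask.any():
            raise ValueError("healthy scenes cannot carry secretion patches")
        if np.any(self.true_reflectance < 0):
            raise ValueError("true reflectance must be non-negative")


@dataclass
class RawHSI:
    """A raw radiance cube plus the gray-panel reference frame."""

    cube: np.ndarray           # (bands, H, W), sensor counts
    grid: WavelengthGrid
    gray_reference: np.ndarray  # (bands, H, W), counts of the 50% panel

    def __post_init__(self):
        if self.cube.shape != self.gray_reference.shape:
            raise ValueError("cube and gray reference must share shape")
        if self.cube.shape[0] != len(self.grid):
            raise ValueError("band count must match the wavelength grid")
        if not np.all(self.gray_reference > 0):
            raise ValueError("gray reference must be strictly positive")


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic study.

    ``effect_size`` is the peak depression (unitless reflectance) of the
    infected lamina inside ``discriminative_band_range``; secretion patches
    supply the broadband visible-range signal independently of it.
    """

    n_healthy_per_session: tuple = DEFAULT_HEALTHY_PER_SESSION
    n_infected_per_session: tuple = DEFAULT_INFECTED_PER_SESSION
    height: int = 96
    width: int = 128
    n_bands: int = 128
    lo_nm: float = 376.0
    hi_nm: float = 1044.0
    discriminative_band_range: tuple = (750.0, 950.0)
    effect_size: float = 0.10
    noise_sd: float = 8.0            # additive sensor noise, counts
    gray_level: float = 2000.0       # gray-panel peak counts
    background_reflectance: float = 0.05
    secretion_reflectance: float = 0.85
    texture_sd: float = 0.05         # within-leaf multiplicative texture
    infected_texture_scale: float = 1.6
    max_secretion_patches: int = 5   # 0 disables honeydew patches entirely
    seed: int = 0
    split_quotas: dict | None = field(default_factory=lambda: dict(DEFAULT_SPLIT_QUOTAS))

    def __post_init__(self):
        if any(n < 0 for n in self.n_healthy_per_session + self.n_infected_per_session):
            raise ValueError("per-session counts must be non-negative")
        lo, hi = self.discriminative_band_range
        if lo < self.lo_nm or hi > self.hi_nm or lo >= hi:
            raise ValueError("discriminative_band_range must lie inside the grid span")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def n_sessions(self) -> int:
        return len(self.n_healthy_per_session)

    def grid(self) -> WavelengthGrid:
        return make_wavelength_grid(self.n_bands, self.lo_nm, self.hi_nm)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        if d.get("split_quotas"):
            d["split_quotas"] = {f"{s}:{c}": list(v) for (s, c), v in d["split_quotas"].items()}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorConfig":
        d = json.loads(text)
        for key in ("n_healthy_per_session", "n_infected_per_session",
                    "discriminative_band_range"):
            if key in d:
                d[key] = tuple(d[key])
        if d.get("split_quotas"):
            d["split_quotas"] = {
                (int(k.split(":")[0]), int(k.split(":")[1])): tuple(v)
                for k, v in d["split_quotas"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

ROLES = ("lamina", "vein", "edge", "secretion")


def _bump_window(nm: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Raised-cosine window supported exactly on [lo, hi]; zero elsewhere."""
    w = np.zeros_like(nm, dtype=float)
    inside = (nm >= lo) & (nm <= hi)
    w[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (nm[inside] - lo) / (hi - lo)))
    return w


def reflectance_spectrum(role: str, class_label: int, grid: WavelengthGrid,
                         config: GeneratorConfig) -> np.ndarray:
    """Noise-free reflectance curve of one tissue role for one class.

    Healthy lamina is a standard green-vegetation curve: low visible
    reflectance with a chlorophyll green bump near 550 nm, a red absorption
    trough near 675 nm, a steep red edge across 700-720 nm and a high NIR
    plateau. The infected lamina differs from the healthy one *only* inside
    ``config.discriminative_band_range``, where the plateau is depressed by a
    raised-cosine bump of peak ``config.effect_size``. Honeydew secretion is
    bright and spectrally flat.
    """
    if role not in ROLES:
        raise ValueError(f"unknown tissue role {role!r}; expected one of {ROLES}")
    if class_label not in (HEALTHY, INFECTED):
        raise ValueError("class_label must be 0 or 1")
    nm = grid.centers
    if role == "secretion":
        return np.full(nm.shape, config.secretion_reflectance)
    base = (0.06
            + 0.06 * np.exp(-0.5 * ((nm - 550.0) / 25.0) ** 2)   # green bump
            - 0.02 * np.exp(-0.5 * ((nm - 675.0) / 15.0) ** 2)   # red trough
            + 0.44 / (1.0 + np.exp(-(nm - 712.0) / 11.0)))       # red edge
    if class_label == INFECTED:
        lo, hi = config.discriminative_band_range
        base = base - config.effect_size * _bump_window(nm, lo, hi)
    if role == "vein":
        base = 0.92 * base + 0.02
    elif role == "edge":
        base = 0.85 * base
    return np.clip(base, 0.0, 1.2)


# ---------------------------------------------------------------------------
# scene geometry
# ---------------------------------------------------------------------------

def _draw_line(mask: np.ndarray, r0: float, c0: float, r1: float, c1: float,
               thickness: int = 1) -> None:
    """Rasterize a thick line segment into a boolean mask (in place)."""
    n = int(max(abs(r1 - r0), abs(c1 - c0), 1)) * 2 + 1
    rr = np.clip(np.round(np.linspace(r0, r1, n)).astype(int), 0, mask.shape[0] - 1)
    cc = np.clip(np.round(np.linspace(c0, c1, n)).astype(int), 0, mask.shape[1] - 1)
    mask[rr, cc] = True
    if thickness > 1:
        struct = np.ones((thickness, thickness), dtype=bool)
        mask |= ndimage.binary_dilation(mask, structure=struct)


def simulate_scene(config: GeneratorConfig, session: int, class_label: int,
                   rng: np.random.Generator) -> SceneTruth:
    """Draw one leaf scene: blob, veins, edge band and (if infected) patches."""
    H, W = config.height, config.width
    if H < 32 or W < 32:
        raise ValueError("scene dimensions must be at least 32x32 pixels")
    if class_label not in (HEALTHY, INFECTED):
        raise ValueError("class_label must be 0 or 1")

    grid = config.grid()
    yy, xx = np.mgrid[0:H, 0:W]
    cy = H / 2.0 + rng.uniform(-0.03, 0.03) * H
    cx = W / 2.0 + rng.uniform(-0.03, 0.03) * W
    ay = H * rng.uniform(0.32, 0.40)
    ax = W * rng.uniform(0.34, 0.42)
    theta = np.arctan2((yy - cy) / ay, (xx - cx) / ax)
    # star-shaped boundary perturbation keeps the blob connected
    k1, k2 = rng.integers(2, 5), rng.integers(5, 8)
    p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
    wobble = 1.0 + 0.06 * np.sin(k1 * theta + p1) + 0.04 * np.sin(k2 * theta + p2)
    r = np.sqrt(((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2)
    leaf = r < wobble

    interior = ndimage.binary_erosion(leaf, iterations=2)
    edge = leaf & ~interior

    # midrib along the long axis plus a few laterals
    vein = np.zeros((H, W), dtype=bool)
    _draw_line(vein, cy - 0.85 * ay, cx, cy + 0.85 * ay, cx)
    n_lat = int(rng.integers(3, 6))
    for i in range(n_lat):
        t = -0.7 + 1.4 * (i + 0.5) / n_lat
        ry = cy + t * 0.85 * ay
        slope = rng.uniform(0.3, 0.7)
        for sgn in (-1, 1):
            _draw_line(vein, ry, cx, ry - slope * 0.5 * ax, cx + sgn * 0.7 * ax)
    vein &= interior

    secretion = np.zeros((H, W), dtype=bool)
    if class_label == INFECTED and config.max_secretion_patches > 0:
        n_patches = int(rng.integers(1, config.max_secretion_patches + 1))
        host = np.argwhere(interior)
        for _ in range(n_patches):
            pr, pc = host[rng.integers(0, len(host))]
            rad = rng.uniform(1.5, max(2.5, min(H, W) / 22.0))
            secretion |= (yy - pr) ** 2 + (xx - pc) ** 2 <= rad ** 2
        secretion &= interior

    # spectral field: background, then lamina/edge/vein/secretion by priority
    spectra = {role: reflectance_spectrum(role, class_label, grid, config)
               for role in ROLES}
    cube = np.full((len(grid), H, W), config.background_reflectance, dtype=np.float32)
    role_map = np.zeros((H, W), dtype=np.int8)            # 0 bg, 1 lamina, 2 edge, 3 vein, 4 secretion
    role_map[leaf] = 1
    role_map[edge] = 2
    role_map[vein] = 3
    role_map[secretion] = 4
    for code, role in ((1, "lamina"), (2, "edge"), (3, "vein"), (4, "secretion")):
        cube[:, role_map == code] = spectra[role][:, None].astype(np.float32)

    # smooth multiplicative texture over leaf tissue (not secretion)
    tex_sd = config.texture_sd * (config.infected_texture_scale
                                  if class_label == INFECTED else 1.0)
    noise = rng.standard_normal((H, W))
    smooth = ndimage.gaussian_filter(noise, sigma=6.0)
    smooth = smooth / max(smooth.std(), 1e-12) * tex_sd + 1.0
    amp = np.clip(smooth, 0.6, 1.4).astype(np.float32)
    tissue = leaf & ~secretion
    cube[:, tissue] *= amp[tissue][None, :]
    np.clip(cube, 0.0, 1.2, out=cube)

    scene = SceneTruth(leaf_mask=leaf, vein_mask=vein, edge_mask=edge,
                       secretion_mask=secretion, class_label=class_label,
                       session=int(session), true_reflectance=cube)
    scene.validate()
    return scene


# ---------------------------------------------------------------------------
# sensor model
# ---------------------------------------------------------------------------

def make_gray_reference(grid: WavelengthGrid, height: int, width: int,
                        config: GeneratorConfig | None = None) -> np.ndarray:
    """Deterministic 50%-panel radiance frame: halogen-like lamp spectrum
    with mild radial vignetting; strictly positive everywhere."""
    level = config.gray_level if config is not None else 2000.0
    nm = grid.centers
    lamp = 0.35 + 0.65 * np.exp(-0.5 * ((nm - 880.0) / 260.0) ** 2)
    yy, xx = np.mgrid[0:height, 0:width]
    ry = (yy - height / 2.0) / (height / 2.0)
    rx = (xx - width / 2.0) / (width / 2.0)
    vignette = 1.0 - 0.10 * (ry ** 2 + rx ** 2)
    return (level * lamp[:, None, None] * vignette[None, :, :]).astype(np.float64)


def render_raw_cube(scene: SceneTruth, grid: WavelengthGrid,
                    config: GeneratorConfig, rng: np.random.Generator) -> RawHSI:
    """Forward sensor model: counts = reflectance * 2 * gray + N(0, noise_sd),
    clipped at zero. With ``noise_sd = 0`` the reflectance calibration
    recovers ``scene.true_reflectance`` exactly."""
    if scene.true_reflectance.shape[0] != len(grid):
        raise ValueError("scene spectral axis does not match the grid")
    H, W = scene.leaf_mask.shape
    gray = make_gray_reference(grid, H, W, config)
    counts = scene.true_reflectance.astype(np.float64) * 2.0 * gray
    if config.noise_sd > 0:
        counts = counts + rng.normal(0.0, config.noise_sd, size=counts.shape)
    np.clip(counts, 0.0, None, out=counts)
    return RawHSI(cube=counts, grid=grid, gray_reference=gray)


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------

def _sample_seed(config_seed: int, index: int) -> int:
    # stable, collision-free for < 100003 samples, and < 2**31
    return (int(config_seed) * 100003 + 7919 * int(index) + 13) % (2 ** 31)


@dataclass
class SyntheticDataset:
    """Lazy dataset: the manifest is materialized, cubes render on demand."""

    config: GeneratorConfig
    manifest: pd.DataFrame  # columns: id, class, session, seed, path

    def __len__(self) -> int:
        return len(self.manifest)

    def scene(self, index: int) -> SceneTruth:
        row = self.manifest.iloc[index]
        rng = np.random.default_rng(int(row["seed"]))
        return simulate_scene(self.config, int(row["session"]), int(row["class"]), rng)

    def sample(self, index: int) -> tuple[RawHSI, SceneTruth]:
        row = self.manifest.iloc[index]
        rng = np.random.default_rng(int(row["seed"]))
        scene = simulate_scene(self.config, int(row["session"]), int(row["class"]), rng)
        raw = render_raw_cube(scene, self.config.grid(), self.config, rng)
        return raw, scene


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Build the manifest of the synthetic study (cubes render lazily).

    Default config: 125 healthy + 131 infected leaves = 256 samples over five
    sessions, matching the reference study's bookkeeping.
    """
    rows = []
    index = 0
    for session in range(1, config.n_sessions + 1):
        for label, count in ((HEALTHY, config.n_healthy_per_session[session - 1]),
                             (INFECTED, config.n_infected_per_session[session - 1])):
            for k in range(count):
                rows.append({
                    "id": f"s{session}_c{label}_{k:03d}",
                    "class": label,
                    "session": session,
                    "seed": _sample_seed(config.seed, index),
                    "path": "",
                })
                index += 1
    if not rows:
        raise ValueError("config yields zero samples")
    manifest = pd.DataFrame(rows, columns=["id", "class", "session", "seed", "path"])
    return SyntheticDataset(config=config, manifest=manifest)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> pd.DataFrame:
    """Materialize raw cubes (ENVI) and masks (PNG) to disk; returns the
    manifest with filled ``path`` column and writes ``manifest.csv`` and
    ``config.json`` alongside."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = dataset.config.grid()
    gray = make_gray_reference(grid, dataset.config.height, dataset.config.width,
                               dataset.config)
    write_envi(outdir / "gray_reference", gray.astype(np.float32), grid.centers)
    manifest = dataset.manifest.copy()
    for i in range(len(dataset)):
        raw, scene = dataset.sample(i)
        stem = outdir / manifest.iloc[i]["id"]
        write_envi(stem, raw.cube.astype(np.float32), grid.centers)
        write_mask_png(stem.with_suffix(".leaf.png"), scene.leaf_mask)
        if scene.secretion_mask.any():
            write_mask_png(stem.with_suffix(".secretion.png"), scene.secretion_mask)
        manifest.iloc[i, manifest.columns.get_loc("path")] = str(stem.with_suffix(".img"))
    manifest.to_csv(outdir / "manifest.csv", index=False)
    (outdir / "config.json").write_text(dataset.config.to_json())
    return manifest
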