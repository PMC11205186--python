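"""Synthetic phase-contrast-like phantoms with ground truth.

Generates field images and pre-cropped single-cell patches for the six
cell-state categories, emulating sparse adherent cells at nominal 20x
magnification. The renderer encodes each category's defining morphology:

* mitosis     - near-circular body with a strong bright rim
* apoptosis   - small shrunken body with peripheral membrane blebs
* interphase  - slightly oblong body with a clear (bright) boundary
* necrosis    - swollen body, larger than interphase, with a faint rim
* senescence  - very large, flat and dark body (interior below background)
* discarded   - two touching cells (a multiplet) sharing one neighbourhood

Every cell carries a bright rim of some strength: in phase contrast the
optical boundary of an adherent cell reads brighter than the mid-gray
background, and the segmentation stage binarizes on exactly that contrast.
Sizes are in pixels at 20x and are chosen so that the smallest class
(apoptosis) still exceeds the segmentation stage's published minimum object
area (2000 px^2 after erosion) -- smaller bodies would be debris by the
pipeline's own definition. All sizes and intensities are configurable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import disk as draw_disk

from .labels import LABEL_ORDER, BIOLOGICAL_LABELS, CellStateLabel, as_label

#: Per-class sampling ranges: full major-axis length (px), minor/major ratio,
#: rim and interior brightness offsets relative to the background level
#: (16-bit counts), rim width (px) and bleb count range (apoptosis only).
CLASS_DEFAULTS: dict[CellStateLabel, dict] = {
    CellStateLabel.MITOSIS: dict(
        major=(60.0, 70.0), ratio=(0.88, 1.0), rim=14000.0, interior=3500.0,
        rim_width=4, blebs=(0, 0),
    ),
    CellStateLabel.APOPTOSIS: dict(
        major=(58.0, 66.0), ratio=(0.85, 1.0), rim=8000.0, interior=-2000.0,
        rim_width=3, blebs=(3, 6),
    ),
    CellStateLabel.INTERPHASE: dict(
        major=(80.0, 92.0), ratio=(0.5, 0.7), rim=9000.0, interior=-3500.0,
        rim_width=3, blebs=(0, 0),
    ),
    CellStateLabel.NECROSIS: dict(
        major=(96.0, 112.0), ratio=(0.75, 0.95), rim=5500.0, interior=-1500.0,
        rim_width=3, blebs=(0, 0),
    ),
    CellStateLabel.SENESCENCE: dict(
        major=(120.0, 140.0), ratio=(0.7, 0.9), rim=5000.0, interior=-6500.0,
        rim_width=3, blebs=(0, 0),
    ),
}

DEFAULT_BACKGROUND = 28000.0
DEFAULT_NOISE_SIGMA = 350.0
#: Cells are placed at least this far from the field border so a default
#: 100 px crop window around any centroid stays inside the field.
DEFAULT_MARGIN = 65
#: Minimum free gap between the rims of distinct (non-multiplet) cells, so
#: that the segmentation stage's dilation cannot bridge neighbours.
MIN_GAP = 10.0


@dataclass(frozen=True)
class PhantomCellSpec:
    """Geometry and intensity of one rendered cell."""

    label: CellStateLabel
    centroid: tuple[float, float]  # (row, col)
    major_axis: float  # full length, px
    minor_axis: float
    orientation: float  # radians
    rim_brightness: float  # offset above background
    interior_brightness: float  # signed offset vs background
    rim_width: int = 3
    bleb_count: int = 0

    def validate(self) -> None:
        label = as_label(self.label)
        if self.minor_axis > self.major_axis:
            raise ValueError("minor_axis cannot exceed major_axis")
        ratio = self.minor_axis / self.major_axis
        if label is CellStateLabel.MITOSIS:
            if ratio < 0.85:
                raise ValueError("mitosis must be near-circular (axis ratio >= 0.85)")
            if self.rim_brightness <= 0:
                raise ValueError("mitosis requires a bright rim")
        elif label is CellStateLabel.APOPTOSIS:
            if self.bleb_count < 2:
                raise ValueError("apoptosis requires bleb_count >= 2")
        elif label is CellStateLabel.INTERPHASE:
            if not (0.4 <= ratio <= 0.8):
                raise ValueError("interphase must be oblong (axis ratio in [0.4, 0.8])")
        elif label is CellStateLabel.SENESCENCE:
            if self.interior_brightness >= 0:
                raise ValueError("senescence interior must be darker than background")

    @property
    def area(self) -> float:
        """Nominal ellipse area (px^2), blebs excluded."""
        return np.pi * (self.major_axis / 2) * (self.minor_axis / 2)


@dataclass
class PhantomGroundTruth:
    """Everything needed to reproduce and score one phantom field."""

    cells: list[PhantomCellSpec]
    image_shape: tuple[int, int]
    background_level: float = DEFAULT_BACKGROUND
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    seed: int = 0

    _COLS = (
        "label", "row", "col", "major_axis", "minor_axis", "orientation",
        "rim_brightness", "interior_brightness", "rim_width", "bleb_count",
    )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    c.label.value, c.centroid[0], c.centroid[1], c.major_axis,
                    c.minor_axis, c.orientation, c.rim_brightness,
                    c.interior_brightness, c.rim_width, c.bleb_count,
                )
                for c in self.cells
            ],
            columns=self._COLS,
        )

    def to_csv(self, path: str | Path) -> None:
        buf = io.StringIO()
        buf.write(f"# image_shape={self.image_shape[0]},{self.image_shape[1]}\n")
        buf.write(f"# background_level={self.background_level!r}\n")
        buf.write(f"# noise_sigma={self.noise_sigma!r}\n")
        buf.write(f"# seed={self.seed}\n")
        self.to_frame().to_csv(buf, index=False, float_format="%.17g")
        Path(path).write_text(buf.getvalue())

    @classmethod
    def from_csv(cls, path: str | Path) -> "PhantomGroundTruth":
        text = Path(path).read_text().splitlines()
        meta = {}
        for line in text:
            if not line.startswith("#"):
                break
            key, val = line[1:].strip().split("=", 1)
            meta[key] = val
        df = pd.read_csv(
            io.StringIO("\n".join(text)), comment="#", float_precision="round_trip"
        )
        cells = [
            PhantomCellSpec(
                label=as_label(r.label),
                centroid=(float(r.row), float(r.col)),
                major_axis=float(r.major_axis),
                minor_axis=float(r.minor_axis),
                orientation=float(r.orientation),
                rim_brightness=float(r.rim_brightness),
                interior_brightness=float(r.interior_brightness),
                rim_width=int(r.rim_width),
                bleb_count=int(r.bleb_count),
            )
            for r in df.itertuples()
        ]
        rows, cols = (int(v) for v in meta["image_shape"].split(","))
        return cls(
            cells=cells,
            image_shape=(rows, cols),
            background_level=float(meta["background_level"]),
            noise_sigma=float(meta["noise_sigma"]),
            seed=int(meta["seed"]),
        )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _ellipse_mask(shape, centroid, a, b, orientation) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    if a <= 0 or b <= 0:
        return mask
    rr, cc = draw_ellipse(
        centroid[0], centroid[1], a, b, shape=shape, rotation=orientation
    )
    mask[rr, cc] = True
    return mask


def render_cell(spec: PhantomCellSpec, canvas_shape: tuple[int, int]) -> np.ndarray:
    """Additive intensity patch (float64) implementing the class morphology.

    The patch is zero on background; add it to a background canvas to place
    the cell. Deterministic given the spec.
    """
    spec = replace(spec, label=as_label(spec.label))
    spec.validate()
    a, b = spec.major_axis / 2.0, spec.minor_axis / 2.0
    w = spec.rim_width
    outer = _ellipse_mask(canvas_shape, spec.centroid, a, b, spec.orientation)
    inner = _ellipse_mask(canvas_shape, spec.centroid, a - w, b - w, spec.orientation)
    patch = np.zeros(canvas_shape, dtype=np.float64)
    patch[inner] = spec.interior_brightness
    patch[outer & ~inner] = spec.rim_brightness
    if spec.bleb_count:
        # Blebs: bright circular protrusions at evenly spaced boundary angles.
        r_bleb = max(4.0, spec.minor_axis / 8.0)
        rot = spec.orientation
        for j in range(spec.bleb_count):
            t = 2 * np.pi * j / spec.bleb_count
            # point on the unrotated ellipse boundary, rotated like the body
            dr0, dc0 = a * np.cos(t), b * np.sin(t)
            dr = dr0 * np.cos(rot) - dc0 * np.sin(rot)
            dc = dr0 * np.sin(rot) + dc0 * np.cos(rot)
            rr, cc = draw_disk(
                (spec.centroid[0] + dr, spec.centroid[1] + dc),
                r_bleb,
                shape=canvas_shape,
            )
            patch[rr, cc] = spec.rim_brightness
    return patch


def sample_spec(
    label: CellStateLabel,
    rng: np.random.Generator,
    centroid: tuple[float, float] = (0.0, 0.0),
    class_params: dict | None = None,
) -> PhantomCellSpec:
    """Draw one cell's geometry from the class's default distributions."""
    label = as_label(label)
    if label is CellStateLabel.DISCARDED:
        raise ValueError(
            "discarded (multiplet) specs are built from two touching cells; "
            "use sample_multiplet"
        )
    p = dict(CLASS_DEFAULTS[label])
    if class_params:
        p.update(class_params)
    major = rng.uniform(*p["major"])
    ratio = rng.uniform(*p["ratio"])
    blebs = int(rng.integers(p["blebs"][0], p["blebs"][1] + 1)) if p["blebs"][1] else 0
    return PhantomCellSpec(
        label=label,
        centroid=centroid,
        major_axis=major,
        minor_axis=major * ratio,
        orientation=float(rng.uniform(0, np.pi)),
        rim_brightness=p["rim"],
        interior_brightness=p["interior"],
        rim_width=p["rim_width"],
        bleb_count=blebs,
    )


def sample_multiplet(
    rng: np.random.Generator, centroid: tuple[float, float]
) -> list[PhantomCellSpec]:
    """Two touching interphase-like cells, both labeled discarded."""
    base = sample_spec(CellStateLabel.INTERPHASE, rng)
    other = sample_spec(CellStateLabel.INTERPHASE, rng)
    # centroid distance below the sum of semi-minor axes -> masks touch
    d = 0.9 * (base.minor_axis + other.minor_axis) / 2.0
    theta = rng.uniform(0, 2 * np.pi)
    c1 = (centroid[0] - d / 2 * np.sin(theta), centroid[1] - d / 2 * np.cos(theta))
    c2 = (centroid[0] + d / 2 * np.sin(theta), centroid[1] + d / 2 * np.cos(theta))
    return [
        replace(base, label=CellStateLabel.DISCARDED, centroid=c1),
        replace(other, label=CellStateLabel.DISCARDED, centroid=c2),
    ]


# ---------------------------------------------------------------------------
# fields and corpora
# ---------------------------------------------------------------------------

def _to_uint16(canvas: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(canvas), 0, 65535).astype(np.uint16)


def generate_field(
    n_cells: int,
    class_mix: dict[CellStateLabel, float] | None = None,
    field_shape: tuple[int, int] = (1000, 1000),
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    background_level: float = DEFAULT_BACKGROUND,
    margin: int = DEFAULT_MARGIN,
    seed: int = 0,
    max_attempts: int = 2000,
) -> tuple[np.ndarray, PhantomGroundTruth]:
    """Render one 16-bit field of sparse cells plus its ground truth.

    ``n_cells`` counts placement events; a 'discarded' event places two
    touching cells (both listed in the ground truth). Placement keeps
    non-multiplet cells separated so their dilated rims cannot merge, and
    keeps every centroid at least ``margin`` px from the border (a low
    confluence field of view). Same seed, same arguments -> identical pixels.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if class_mix is None:
        class_mix = {l: 1.0 / len(BIOLOGICAL_LABELS) for l in BIOLOGICAL_LABELS}
    class_mix = {as_label(k): float(v) for k, v in class_mix.items()}
    total = sum(class_mix.values())
    if n_cells > 0 and abs(total - 1.0) > 1e-6:
        raise ValueError(f"class_mix must sum to 1, got {total}")

    rng = np.random.default_rng(seed)
    rows, cols = field_shape
    labels = list(class_mix)
    probs = np.array([class_mix[l] for l in labels])
    placed: list[PhantomCellSpec] = []

    def collides(spec: PhantomCellSpec, others: list[PhantomCellSpec]) -> bool:
        for o in others:
            d = np.hypot(
                spec.centroid[0] - o.centroid[0], spec.centroid[1] - o.centroid[1]
            )
            if d < (spec.major_axis + o.major_axis) / 2.0 + MIN_GAP:
                return True
        return False

    for _ in range(n_cells):
        lab = labels[int(rng.choice(len(labels), p=probs))]
        ok = False
        for _attempt in range(max_attempts):
            centroid = (
                float(rng.uniform(margin, rows - margin)),
                float(rng.uniform(margin, cols - margin)),
            )
            if lab is CellStateLabel.DISCARDED:
                group = sample_multiplet(rng, centroid)
            else:
                group = [sample_spec(lab, rng, centroid)]
            # multiplet members may touch each other but nothing else
            prior = placed
            if all(not collides(g, prior) for g in group):
                placed.extend(group)
                ok = True
                break
        if not ok:
            raise ValueError(
                f"could not place {n_cells} cells at field shape {field_shape}: "
                "requested density is incompatible with the non-overlap constraint"
            )

    canvas = background_level + rng.normal(0.0, noise_sigma, field_shape)
    for spec in placed:
        canvas += render_cell(spec, field_shape)
    image = _to_uint16(canvas)
    truth = PhantomGroundTruth(
        cells=placed,
        image_shape=tuple(field_shape),
        background_level=background_level,
        noise_sigma=noise_sigma,
        seed=seed,
    )
    return image, truth


def render_crop(
    label: CellStateLabel,
    rng: np.random.Generator,
    crop_size: int = 100,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    background_level: float = DEFAULT_BACKGROUND,
) -> tuple[np.ndarray, list[PhantomCellSpec]]:
    """One labeled crop_size x crop_size patch with the cell at its centre."""
    label = as_label(label)
    shape = (crop_size, crop_size)
    centre = ((crop_size - 1) / 2.0, (crop_size - 1) / 2.0)
    if label is CellStateLabel.DISCARDED:
        specs = sample_multiplet(rng, centre)
    else:
        specs = [sample_spec(label, rng, centre)]
    canvas = background_level + rng.normal(0.0, noise_sigma, shape)
    for s in specs:
        canvas += render_cell(s, shape)
    return _to_uint16(canvas), specs


def generate_training_corpus(
    n_per_class: int,
    seed: int = 0,
    crop_size: int = 100,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    background_level: float = DEFAULT_BACKGROUND,
) -> tuple[np.ndarray, list[CellStateLabel]]:
    """Balanced labeled corpus: n_per_class crops for each of the 6 classes.

    Returns (crops, labels) with crops of shape (6*n_per_class, crop_size,
    crop_size) uint16, grouped by class in the canonical label order.
    Same seed -> identical pixels and label sequence.
    """
    if n_per_class < 0:
        raise ValueError("n_per_class must be >= 0")
    rng = np.random.default_rng(seed)
    crops = np.empty((6 * n_per_class, crop_size, crop_size), dtype=np.uint16)
    labels: list[CellStateLabel] = []
    i = 0
    for label in LABEL_ORDER:
        for _ in range(n_per_class):
            crops[i], _ = render_crop(
                label, rng, crop_size, noise_sigma, background_level
            )
            labels.append(label)
            i += 1
    return crops, labels


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------

def save_corpus(
    directory: str | Path, crops: np.ndarray, labels: list[CellStateLabel]
) -> pd.DataFrame:
    """One subdirectory of TIFF crops per category plus an index.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    counters: dict[str, int] = {}
    for crop, label in zip(crops, labels):
        label = as_label(label)
        k = counters.get(label.value, 0)
        counters[label.value] = k + 1
        sub = directory / label.value
        sub.mkdir(exist_ok=True)
        name = f"{label.value}/{label.value}_{k:05d}.tif"
        tifffile.imwrite(directory / name, np.asarray(crop, dtype=np.uint16))
        rows.append((name, label.value))
    index = pd.DataFrame(rows, columns=["path", "label"])
    index.to_csv(directory / "index.csv", index=False)
    return index


def load_corpus(directory: str | Path) -> tuple[np.ndarray, list[CellStateLabel]]:
    """Read a corpus directory back; index.csv is the authoritative labeling."""
    directory = Path(directory)
    index = pd.read_csv(directory / "index.csv")
    crops = np.stack(
        [tifffile.imread(directory / p) for p in index["path"]], axis=0
    )
    labels = [as_label(l) for l in index["label"]]
    return crops, labels
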