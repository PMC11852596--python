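"""Synthetic AFM images of collagen-type filaments with exact ground truth.

A filament is sampled as a discrete 2-D worm-like chain (WLC): equal-length
segments whose successive turning angles are independent zero-mean Gaussians
with variance ``segment_length / persistence_length``.  Under this convention
the tangent autocorrelation decays as exp(-s / (2 * persistence_length)),
the standard planar WLC for molecules equilibrated on a flat substrate
(mica deposition is quasi-2-D).  The "collagen monomer" preset uses a 300 nm
contour — the theoretical length of the type I collagen monomer — with a
6000 nm persistence length, giving the near-straight rods seen in AFM.

Rendering emulates the microscope: each chain becomes a half-cylindrical
height profile of the given tube radius, profiles of all chains are combined
by a pixel-wise maximum over a flat substrate, the field is convolved with an
isotropic Gaussian (finite-tip broadening), and i.i.d. Gaussian height noise
is added.  Every generated filament carries its true centerline polyline and
true lengths so downstream tracing and measurement can be validated exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import cdist

from .errors import InvalidSpecificationError, PlacementError
from .image import AFMImage, rotate_points_90, write_afm_tiff

__all__ = [
    "FilamentSpec", "ImageSpec", "FilamentTruth", "SyntheticDataset",
    "collagen_monomer_preset", "sample_wlc_chain", "render_image",
    "generate_dataset", "save_dataset", "load_ground_truth",
]

_PLACEMENT_RETRIES = 100  # rejection-sampling attempts per filament


@dataclass(frozen=True)
class FilamentSpec:
    """Geometry of one simulated molecule.

    All lengths in nm.  ``segment_length`` is the WLC discretisation step and
    must resolve the chain (at most contour_length / 10).
    """

    contour_length: float = 300.0
    persistence_length: float = 6000.0
    segment_length: float = 3.0
    height: float = 1.5
    tube_radius: float = 1.5

    def __post_init__(self) -> None:
        for name in ("contour_length", "persistence_length",
                     "segment_length", "height", "tube_radius"):
            if getattr(self, name) <= 0:
                raise InvalidSpecificationError(f"{name} must be > 0")
        if self.segment_length > self.contour_length / 10:
            raise InvalidSpecificationError(
                "segment_length must be <= contour_length / 10")


@dataclass(frozen=True)
class ImageSpec:
    """Acquisition geometry of one simulated scan.

    ``tip_sigma`` is the Gaussian tip-broadening sigma and ``noise_sigma``
    the additive height-noise sigma, both in nm.  ``margin`` (px) keeps
    filaments away from the border; ``min_separation`` (nm) keeps them from
    touching each other.
    """

    size: int = 512
    pixel_size: float = 2.0
    tip_sigma: float = 4.0
    noise_sigma: float = 0.1
    background_height: float = 0.0
    margin: int = 20
    min_separation: float = 30.0
    filaments_per_image: tuple[int, int] = (1, 5)

    def __post_init__(self) -> None:
        if self.size < 64:
            raise InvalidSpecificationError("size must be >= 64")
        if self.pixel_size <= 0:
            raise InvalidSpecificationError("pixel_size must be > 0")
        if self.tip_sigma < 0 or self.noise_sigma < 0:
            raise InvalidSpecificationError("sigmas must be >= 0")
        if self.margin < 0:
            raise InvalidSpecificationError("margin must be >= 0")
        lo, hi = self.filaments_per_image
        if not (1 <= lo <= hi):
            raise InvalidSpecificationError("filaments_per_image must satisfy 1 <= lo <= hi")


def collagen_monomer_preset() -> tuple[FilamentSpec, ImageSpec]:
    """The default simulation conditions for type I collagen monomers."""
    return FilamentSpec(), ImageSpec()


@dataclass(frozen=True)
class FilamentTruth:
    """Ground truth for one placed filament."""

    id: str
    image_id: str
    polyline: np.ndarray          # (n+1, 2) nm, image coordinates
    contour_length: float         # nm, sum of segment lengths
    end_to_end: float             # nm
    base_id: str | None = None    # id of the 0-degree partner for rotated scans


@dataclass
class SyntheticDataset:
    images: list[AFMImage]
    truths: list[FilamentTruth]
    n_dropped: int = 0
    filament_spec: FilamentSpec | None = None
    image_spec: ImageSpec | None = None
    seed: int | None = None

    def truths_for(self, image_id: str) -> list[FilamentTruth]:
        return [t for t in self.truths if t.image_id == image_id]


def polyline_arc_length(polyline: np.ndarray) -> float:
    seg = np.diff(np.asarray(polyline, float), axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


def sample_wlc_chain(spec: FilamentSpec, rng: np.random.Generator) -> np.ndarray:
    """Sample a discrete planar worm-like chain.

    Returns an (n+1, 2) polyline starting at the origin with a uniformly
    random initial direction; n = round(contour_length / segment_length)
    equal segments whose total length is exactly the contour length.
    """
    n = int(round(spec.contour_length / spec.segment_length))
    ds = spec.contour_length / n
    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    turns = rng.normal(0.0, np.sqrt(ds / spec.persistence_length), size=n - 1)
    angles = theta0 + np.concatenate([[0.0], np.cumsum(turns)])
    steps = ds * np.column_stack([np.cos(angles), np.sin(angles)])
    return np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])


def _point_segment_distances(points: np.ndarray, a: np.ndarray,
                             b: np.ndarray) -> np.ndarray:
    """Min distance from each point to any of the segments (a[i], b[i])."""
    ab = b - a                                     # (k, 2)
    ab2 = np.maximum(np.sum(ab * ab, axis=1), 1e-300)
    ap = points[:, None, :] - a[None, :, :]        # (m, k, 2)
    t = np.clip(np.einsum("mkd,kd->mk", ap, ab) / ab2, 0.0, 1.0)
    closest = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d = np.hypot(points[:, None, 0] - closest[:, :, 0],
                 points[:, None, 1] - closest[:, :, 1])
    return d.min(axis=1)


def _check_placement(polylines: list[np.ndarray], spec: ImageSpec,
                     tube_radius: float) -> None:
    extent = spec.size * spec.pixel_size
    lo = spec.margin * spec.pixel_size + tube_radius
    hi = extent - spec.margin * spec.pixel_size - tube_radius
    for p in polylines:
        if p[:, 0].min() < lo or p[:, 0].max() > hi \
                or p[:, 1].min() < lo or p[:, 1].max() > hi:
            raise PlacementError("filament violates the image margin")
    for i in range(len(polylines)):
        for j in range(i + 1, len(polylines)):
            if cdist(polylines[i], polylines[j]).min() < spec.min_separation:
                raise PlacementError("filaments closer than min_separation")


def render_image(filaments: list[np.ndarray], spec: ImageSpec,
                 rng: np.random.Generator | None = None,
                 filament_spec: FilamentSpec | None = None,
                 id: str = "image") -> AFMImage:
    """Rasterise placed polylines into a noisy, tip-broadened heightmap.

    Height before blur is ``background + max_f height * sqrt(1 - (d/r)^2)``
    with d the distance to filament f's polyline and r its tube radius (a
    half-cylinder cross-section lying on the substrate).
    """
    fspec = filament_spec or FilamentSpec()
    _check_placement(filaments, spec, fspec.tube_radius)

    px = spec.pixel_size
    signal = np.zeros((spec.size, spec.size))
    pad = fspec.tube_radius / px + 1.0
    for poly in filaments:
        cmin = max(int(np.floor(poly[:, 0].min() / px - pad)), 0)
        cmax = min(int(np.ceil(poly[:, 0].max() / px + pad)), spec.size - 1)
        rmin = max(int(np.floor(poly[:, 1].min() / px - pad)), 0)
        rmax = min(int(np.ceil(poly[:, 1].max() / px + pad)), spec.size - 1)
        rows, cols = np.mgrid[rmin:rmax + 1, cmin:cmax + 1]
        centers = np.column_stack([(cols.ravel() + 0.5) * px,
                                   (rows.ravel() + 0.5) * px])
        d = _point_segment_distances(centers, poly[:-1], poly[1:])
        prof = fspec.height * np.sqrt(np.clip(
            1.0 - (d / fspec.tube_radius) ** 2, 0.0, None))
        region = signal[rmin:rmax + 1, cmin:cmax + 1]
        np.maximum(region, prof.reshape(rows.shape), out=region)

    if spec.tip_sigma > 0:
        signal = gaussian_filter(signal, sigma=spec.tip_sigma / px)
    heights = spec.background_height + signal
    if spec.noise_sigma > 0:
        if rng is None:
            raise ValueError("rng required when noise_sigma > 0")
        heights = heights + rng.normal(0.0, spec.noise_sigma, heights.shape)
    return AFMImage(heights, px, id=id)


def _place_chain(chain: np.ndarray, spec: ImageSpec, tube_radius: float,
                 rng: np.random.Generator) -> np.ndarray | None:
    """Random rigid placement inside the margins; None if it cannot fit."""
    phi = rng.uniform(0.0, 2.0 * np.pi)
    rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    rotated = chain @ rot.T
    extent = spec.size * spec.pixel_size
    lo = spec.margin * spec.pixel_size + tube_radius
    hi = extent - spec.margin * spec.pixel_size - tube_radius
    span = rotated.max(axis=0) - rotated.min(axis=0)
    free = (hi - lo) - span
    if free[0] <= 0 or free[1] <= 0:
        return None
    offset = lo - rotated.min(axis=0) + rng.uniform(0.0, 1.0, 2) * free
    return rotated + offset


def generate_dataset(filament_spec: FilamentSpec, image_spec: ImageSpec,
                     n_images: int, seed: int,
                     rotate_pairs: bool = False) -> SyntheticDataset:
    """Generate a deterministic dataset of images plus exact ground truth.

    With ``rotate_pairs`` every image is emitted twice: the 0-degree scan and
    its 90-degree (counter-clockwise) rotation, whose ground-truth polylines
    are transformed accordingly and linked via ``base_id``.  Filaments that
    cannot be placed after bounded retries are dropped and counted in
    ``n_dropped``.
    """
    rng = np.random.default_rng(seed)
    images: list[AFMImage] = []
    truths: list[FilamentTruth] = []
    n_dropped = 0
    width_nm = image_spec.size * image_spec.pixel_size

    for img_idx in range(n_images):
        image_id = f"img_{img_idx:03d}"
        lo, hi = image_spec.filaments_per_image
        n_fil = int(rng.integers(lo, hi + 1))
        placed: list[np.ndarray] = []
        for _ in range(n_fil):
            for _ in range(_PLACEMENT_RETRIES):
                chain = sample_wlc_chain(filament_spec, rng)
                poly = _place_chain(chain, image_spec,
                                    filament_spec.tube_radius, rng)
                if poly is None:
                    continue
                if all(cdist(poly, q).min() >= image_spec.min_separation
                       for q in placed):
                    placed.append(poly)
                    break
            else:
                n_dropped += 1

        image = render_image(placed, image_spec, rng,
                             filament_spec=filament_spec, id=image_id)
        images.append(image)
        img_truths = []
        for k, poly in enumerate(placed):
            tid = f"{image_id}:{k}"
            img_truths.append(FilamentTruth(
                id=tid, image_id=image_id, polyline=poly,
                contour_length=polyline_arc_length(poly),
                end_to_end=float(np.hypot(*(poly[-1] - poly[0])))))
        truths.extend(img_truths)

        if rotate_pairs:
            rot_image = image.rot90()
            images.append(rot_image)
            for t in img_truths:
                truths.append(FilamentTruth(
                    id=f"{t.id}_rot90", image_id=rot_image.id,
                    polyline=rotate_points_90(t.polyline, width_nm),
                    contour_length=t.contour_length,
                    end_to_end=t.end_to_end, base_id=t.id))

    return SyntheticDataset(images=images, truths=truths, n_dropped=n_dropped,
                            filament_spec=filament_spec, image_spec=image_spec,
                            seed=seed)


def save_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Write one float TIFF per image, ground_truth.json and a config echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for image in dataset.images:
        write_afm_tiff(image, out / f"{image.id}.tif")
    records = [{
        "id": t.id, "image_id": t.image_id, "base_id": t.base_id,
        "polyline_nm": np.asarray(t.polyline).tolist(),
        "contour_length_nm": t.contour_length,
        "end_to_end_nm": t.end_to_end,
    } for t in dataset.truths]
    (out / "ground_truth.json").write_text(
        json.dumps({"n_dropped": dataset.n_dropped, "filaments": records}))
    cfg = {
        "seed": dataset.seed,
        "filament_spec": dataclasses.asdict(dataset.filament_spec)
        if dataset.filament_spec else None,
        "image_spec": dataclasses.asdict(dataset.image_spec)
        if dataset.image_spec else None,
    }
    (out / "config.yaml").write_text(yaml.safe_dump(cfg))


def load_ground_truth(path: str | Path) -> list[FilamentTruth]:
    """Read a ground_truth.json written by :func:`save_dataset`."""
    data = json.loads(Path(path).read_text())
    return [FilamentTruth(
        id=r["id"], image_id=r["image_id"], base_id=r.get("base_id"),
        polyline=np.asarray(r["polyline_nm"], float),
        contour_length=float(r["contour_length_nm"]),
        end_to_end=float(r["end_to_end_nm"])) for r in data["filaments"]]
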