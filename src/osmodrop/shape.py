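"""Per-frame worm segmentation and equivalent-ellipse shape descriptors.

The central primitive of the droplet assay is the *equivalent ellipse*: the
ellipse whose normalized second central moments match those of the
segmented worm silhouette.  Its eccentricity e = sqrt(1 − (b/a)²) is close
to 1 for an elongated, swimming worm and drops sharply when the body curls
into an Ω bend or a deep reversal fold, which is what the turn caller
thresholds on.

Conventions
-----------
* Coordinates are (row, col) with the origin at the top-left pixel center.
* Axes are ``a = 2·sqrt(λ1)``, ``b = 2·sqrt(λ2)`` from the eigenvalues
  λ1 ≥ λ2 of the normalized second-moment (covariance) matrix, the
  convention under which a solid disk has e = 0 and a thin rod e → 1.
* Masks are binary; holes are filled before moments are taken because a
  self-overlapping Ω posture can enclose background.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label


class EmptyMaskError(ValueError):
    """No foreground component of at least ``min_area`` pixels was found."""


class DegenerateShapeError(ValueError):
    """Mask too small or collinear for an ellipse fit."""


@dataclass
class ShapeMetrics:
    """Equivalent-ellipse descriptors of one segmented frame.

    ``eccentricity`` is dimensionless in [0, 1); ``orientation`` is the
    angle of the major axis in radians, mapped to (−π/2, π/2], measured
    from the row axis toward the column axis.
    """

    centroid: tuple[float, float]
    semi_major: float
    semi_minor: float
    orientation: float
    eccentricity: float
    area: float


def segment_frame(frame: np.ndarray, policy: str = "otsu",
                  threshold: float | None = None,
                  min_area: int = 10) -> np.ndarray:
    """Segment the worm from a grayscale frame.

    Parameters
    ----------
    frame
        2-D grayscale raster with the worm brighter than the background.
    policy
        ``"otsu"`` (global Otsu threshold) or ``"fixed"`` (use ``threshold``).
    min_area
        Smallest acceptable foreground component, px.  Below this an
        :class:`EmptyMaskError` is raised so that a lost worm is flagged
        rather than silently producing garbage moments.

    Returns
    -------
    Binary mask: the largest 8-connected foreground component, holes filled.
    """
    frame = np.asarray(frame)
    if policy == "otsu":
        if frame.max() == frame.min():
            raise EmptyMaskError("constant frame: Otsu threshold undefined")
        thr = threshold_otsu(frame)
    elif policy == "fixed":
        if threshold is None:
            raise ValueError("fixed policy requires an explicit threshold")
        thr = threshold
    else:
        raise ValueError(f"unknown segmentation policy {policy!r}")
    fg = frame > thr
    if not fg.any():
        raise EmptyMaskError("no foreground pixels above threshold")
    labels, n = label(fg, connectivity=2, return_num=True)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best = int(sizes.argmax())
    if sizes[best] < min_area:
        raise EmptyMaskError(
            f"largest component has {sizes[best]} px < min_area={min_area}")
    mask = labels == best
    return ndimage.binary_fill_holes(mask)


def mask_moments(mask: np.ndarray) -> tuple[float, tuple[float, float], np.ndarray]:
    """Zeroth moment, centroid and 2×2 central second-moment matrix.

    The covariance is C = [[μ20, μ11], [μ11, μ02]]/μ00 over (row, col)
    pixel-center coordinates.  Exact (integer-accumulated where possible);
    the brute-force double loop in the test suite must agree to the ulp.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    mu00 = float(rows.size)
    if mu00 == 0:
        raise EmptyMaskError("empty mask has no moments")
    r0 = rows.mean()
    c0 = cols.mean()
    dr = rows - r0
    dc = cols - c0
    cov = np.array([[np.dot(dr, dr), np.dot(dr, dc)],
                    [np.dot(dr, dc), np.dot(dc, dc)]]) / mu00
    return mu00, (r0, c0), cov


def fit_equivalent_ellipse(mask: np.ndarray, *,
                           weights: np.ndarray | None = None) -> ShapeMetrics:
    """Fit the equivalent ellipse of a binary mask.

    Optionally, ``weights`` (same shape as the mask, e.g. grayscale
    intensities) makes the moments intensity-weighted over the masked
    region; by default every foreground pixel carries unit mass.

    Raises :class:`DegenerateShapeError` for single-pixel or collinear
    masks, for which no ellipse is defined.
    """
    mask = np.asarray(mask, dtype=bool)
    if weights is None:
        mu00, (r0, c0), cov = mask_moments(mask)
    else:
        w = np.asarray(weights, dtype=float)[mask]
        rows, cols = np.nonzero(mask)
        mu00 = float(w.sum())
        if mu00 <= 0:
            raise EmptyMaskError("non-positive total weight")
        r0 = float(np.dot(w, rows) / mu00)
        c0 = float(np.dot(w, cols) / mu00)
        dr = rows - r0
        dc = cols - c0
        cov = np.array([[np.dot(w, dr * dr), np.dot(w, dr * dc)],
                        [np.dot(w, dr * dc), np.dot(w, dc * dc)]]) / mu00
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending
    lam2, lam1 = float(eigvals[0]), float(eigvals[1])
    if lam1 <= 0 or lam2 <= 0:
        raise DegenerateShapeError(
            "degenerate mask (single pixel or collinear): no ellipse")
    a = 2.0 * np.sqrt(lam1)
    b = 2.0 * np.sqrt(lam2)
    ecc = float(np.sqrt(1.0 - lam2 / lam1))
    vr, vc = eigvecs[:, 1]  # principal eigenvector, (row, col)
    theta = float(np.arctan2(vc, vr))
    if theta <= -np.pi / 2:
        theta += np.pi
    elif theta > np.pi / 2:
        theta -= np.pi
    return ShapeMetrics(centroid=(float(r0), float(c0)), semi_major=a,
                        semi_minor=b, orientation=theta, eccentricity=ecc,
                        area=float(mask.sum()))


def measure_body_area(mask: np.ndarray, pixel_size: float = 1.0) -> float:
    """Body area: foreground pixel count × pixel_size² (μm² if calibrated)."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise EmptyMaskError("empty mask has no area")
    return n * pixel_size ** 2


def metrics_table(stack, policy: str = "otsu", threshold: float | None = None,
                  min_area: int = 10):
    """Per-frame shape metrics for a whole stack as a tidy DataFrame.

    Frames where segmentation or the ellipse fit fails are *flagged*
    (``flagged=True``, metric columns NaN), never dropped, so downstream
    event calling can treat them as missing rather than as shape changes.
    """
    import pandas as pd

    records = []
    for i, frame in enumerate(stack):
        rec = {"frame": i, "time_s": i / stack.frame_rate_hz, "flagged": False}
        try:
            mask = segment_frame(frame, policy=policy, threshold=threshold,
                                 min_area=min_area)
            m = fit_equivalent_ellipse(mask)
            rec.update(centroid_r=m.centroid[0], centroid_c=m.centroid[1],
                       a=m.semi_major, b=m.semi_minor,
                       orientation=m.orientation,
                       eccentricity=m.eccentricity,
                       area=m.area * stack.pixel_size ** 2)
        except (EmptyMaskError, DegenerateShapeError):
            rec.update(centroid_r=np.nan, centroid_c=np.nan, a=np.nan,
                       b=np.nan, orientation=np.nan, eccentricity=np.nan,
                       area=np.nan, flagged=True)
        records.append(rec)
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Blinded renaming for manual area measurements


def blind_rename(file_list: list[str], seed: int) -> tuple[list[str], dict[str, str]]:
    """Seeded blinded renaming of image files for unbiased manual tracing.

    Returns the new names, in randomized presentation order, plus the
    sealed mapping ``{blinded name -> original name}``.  Blinded names are
    ``blind_000.ext`` ... and carry no condition information.  The caller
    is expected to write the mapping somewhere the measurer cannot see
    (:func:`seal_mapping`) and decode afterwards with :func:`unseal`.
    """
    if len(set(file_list)) != len(file_list):
        raise ValueError("file names must be unique")
    if not file_list:
        return [], {}
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(file_list))
    width = max(3, len(str(len(file_list) - 1)))
    renamed = []
    mapping: dict[str, str] = {}
    for new_idx, old_idx in enumerate(order):
        old = file_list[int(old_idx)]
        suffix = Path(old).suffix
        new = f"blind_{new_idx:0{width}d}{suffix}"
        if new in mapping:
            raise ValueError(f"name collision after renaming: {new}")
        mapping[new] = old
        renamed.append(new)
    return renamed, mapping


def seal_mapping(mapping: dict[str, str], path: str | Path) -> None:
    """Write the blinded-name mapping to a separate sealed JSON file."""
    Path(path).write_text(json.dumps(mapping, indent=2, sort_keys=True))


def unseal(path: str | Path) -> dict[str, str]:
    """Recover the blinded-name mapping written by :func:`seal_mapping`."""
    return json.loads(Path(path).read_text())


def blind_rename_files(paths: list[str | Path], seed: int, out_dir: str | Path,
                       mapping_path: str | Path) -> list[Path]:
    """Copy files under blinded names into ``out_dir`` and seal the mapping."""
    import shutil

    paths = [Path(p) for p in paths]
    renamed, mapping = blind_rename([p.name for p in paths], seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_name = {p.name: p for p in paths}
    out_paths = []
    for new in renamed:
        src = by_name[mapping[new]]
        dst = out_dir / new
        if dst.exists():
            raise ValueError(f"name collision after renaming: {dst}")
        shutil.copyfile(src, dst)
        out_paths.append(dst)
    seal_mapping(mapping, mapping_path)
    return out_paths
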