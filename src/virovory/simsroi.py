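"""nanoSIMS-style ion-image stack processing.

A raster analysis acquires secondary-ion counts for four masses
(12C2-, 13C12C-, 12C14N-, 12C15N-) over repeated scans ("cycles") of a
fixed field of view, typically a 20 x 20 um area imaged at 256 x 256
pixels with a 1 ms pixel dwell over 20-30 cycles.  This module turns such
stacks into per-region isotope statistics:

* integer-pixel alignment of cycles against the first cycle (stage drift),
* optional non-paralyzable dead-time correction of count rates,
* automatic particle segmentation on the CN- channel (biomass carries
  nitrogen; the polycarbonate filter substrate does not),
* hotspot finding for protist-scale (4-50 um) features, and
* per-ROI isotope ratios computed cycle by cycle (count sums within the
  ROI per cycle), summarised as mean and standard error across cycles.

Sub-pixel registration is deliberately avoided: interpolating would
redistribute integer ion counts and bias low-count ratio statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from skimage import measure

from virovory.isotope import IsotopeConstants, IsotopeMeasurement

__all__ = [
    "MASS_ORDER",
    "IonImageStack",
    "ROI",
    "ROIIsotopeRecord",
    "align_cycles",
    "deadtime_correct",
    "segment_particles",
    "find_hotspots",
    "roi_isotope_stats",
    "write_roi_records_csv",
]

#: Canonical mass order along the first stack axis.
MASS_ORDER: tuple[str, ...] = ("12C2", "13C12C", "12C14N", "12C15N")
_MASS_INDEX = {name: i for i, name in enumerate(MASS_ORDER)}

#: Default raster geometry: 20 um / 256 px.
DEFAULT_PIXEL_SIZE_NM = 20_000.0 / 256.0


@dataclass(frozen=True)
class IonImageStack:
    """Per-cycle, per-mass ion-count rasters sharing one geometry.

    ``counts`` has shape (4, n_cycles, height, width) in :data:`MASS_ORDER`
    order.  Raw acquisitions are integer counts; dead-time-corrected
    stacks hold real values.  ``valid`` marks pixels usable in every mass
    (False for pixels rolled out of frame by alignment or saturated in
    dead-time correction).
    """

    counts: np.ndarray
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    dwell_ms: float = 1.0
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 4 or counts.shape[0] != len(MASS_ORDER):
            raise ValueError(
                f"counts must have shape (4, n_cycles, h, w), got {counts.shape}"
            )
        if np.any(counts < 0) or np.any(~np.isfinite(counts)):
            raise ValueError("ion counts must be finite and >= 0")
        if self.pixel_size_nm <= 0 or self.dwell_ms <= 0:
            raise ValueError("pixel_size_nm and dwell_ms must be positive")
        object.__setattr__(self, "counts", counts)
        if self.valid is not None:
            valid = np.asarray(self.valid, dtype=bool)
            if valid.shape != counts.shape[1:]:
                raise ValueError("valid mask must have shape (n_cycles, h, w)")
            object.__setattr__(self, "valid", valid)

    @property
    def n_cycles(self) -> int:
        return self.counts.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[2:]

    @property
    def pixel_area_um2(self) -> float:
        return (self.pixel_size_nm / 1000.0) ** 2

    def mass(self, name: str) -> np.ndarray:
        """Cycle stack (n_cycles, h, w) for one mass."""
        return self.counts[_MASS_INDEX[name]]

    def valid_mask(self) -> np.ndarray:
        if self.valid is None:
            return np.ones(self.counts.shape[1:], dtype=bool)
        return self.valid

    def cycle_summed(self, names: Sequence[str]) -> np.ndarray:
        """Sum of the named masses over all cycles, invalid pixels excluded."""
        valid = self.valid_mask()
        total = np.zeros(self.shape, dtype=float)
        for name in names:
            total += np.where(valid, self.mass(name), 0.0).sum(axis=0)
        return total

    # -- I/O: multi-page TIFF (mass-major, cycle-minor) + JSON sidecar ----

    def save_tiff(self, tiff_path, sidecar_path=None) -> None:
        import tifffile

        pages = self.counts.reshape(-1, *self.shape)
        tifffile.imwrite(tiff_path, pages.astype(np.float32))
        meta = {
            "mass_order": list(MASS_ORDER),
            "n_cycles": self.n_cycles,
            "pixel_size_nm": self.pixel_size_nm,
            "dwell_ms": self.dwell_ms,
        }
        if sidecar_path is None:
            sidecar_path = str(tiff_path) + ".json"
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load_tiff(cls, tiff_path, sidecar_path=None) -> "IonImageStack":
        import tifffile

        if sidecar_path is None:
            sidecar_path = str(tiff_path) + ".json"
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        if meta["mass_order"] != list(MASS_ORDER):
            raise ValueError(f"unexpected mass order {meta['mass_order']}")
        pages = tifffile.imread(tiff_path)
        n_cycles = int(meta["n_cycles"])
        counts = np.asarray(pages).reshape(len(MASS_ORDER), n_cycles, *pages.shape[-2:])
        return cls(
            counts=counts,
            pixel_size_nm=float(meta["pixel_size_nm"]),
            dwell_ms=float(meta["dwell_ms"]),
        )


@dataclass(frozen=True)
class ROI:
    """A pixel-set region of interest (0-based (row, col) coordinates)."""

    id: str
    pixels: frozenset
    source: str  # auto_threshold | hotspot | manual
    area_um2: float

    def __post_init__(self) -> None:
        if not self.pixels:
            raise ValueError("ROI must contain at least one pixel")
        if self.source not in ("auto_threshold", "hotspot", "manual"):
            raise ValueError(f"unknown ROI source {self.source!r}")

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        rows, cols = zip(*self.pixels)
        m[list(rows), list(cols)] = True
        return m

    def indices(self) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = zip(*sorted(self.pixels))
        return np.array(rows), np.array(cols)

    @classmethod
    def from_mask(
        cls, mask: np.ndarray, roi_id: str, source: str = "manual", pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    ) -> "ROI":
        pixels = frozenset(zip(*np.nonzero(mask)))
        area = len(pixels) * (pixel_size_nm / 1000.0) ** 2
        return cls(id=roi_id, pixels=pixels, source=source, area_um2=area)

    # Run-length encoding over the flattened row-major mask.
    def to_rle(self, shape: tuple[int, int]) -> dict:
        flat = self.mask(shape).ravel()
        edges = np.flatnonzero(np.diff(np.concatenate([[0], flat.view(np.int8), [0]])))
        starts, ends = edges[::2], edges[1::2]
        return {
            "id": self.id,
            "source": self.source,
            "shape": list(shape),
            "runs": [[int(s), int(e - s)] for s, e in zip(starts, ends)],
        }

    @classmethod
    def from_rle(cls, rle: dict, pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM) -> "ROI":
        shape = tuple(rle["shape"])
        flat = np.zeros(int(np.prod(shape)), dtype=bool)
        for start, length in rle["runs"]:
            flat[start : start + length] = True
        return cls.from_mask(flat.reshape(shape), rle["id"], rle["source"], pixel_size_nm)


@dataclass(frozen=True)
class ROIIsotopeRecord:
    """Ratio-by-cycle statistics and derived isotope values for one ROI.

    Per-cycle ratios are count sums over ROI pixels (numerator mass over
    denominator mass); cycles whose denominator sum is zero are excluded
    (NaN in the ratio arrays) and counted.  ``usable`` is False when no
    cycle has a nonzero denominator for either element.
    """

    roi_id: str
    carbon_ratios: np.ndarray  # 13C12C / 12C2 per cycle
    nitrogen_ratios: np.ndarray  # 12C15N / 12C14N per cycle
    carbon_ratio_mean: float
    carbon_ratio_sem: float
    nitrogen_ratio_mean: float
    nitrogen_ratio_sem: float
    n_cycles_used_carbon: int
    n_cycles_used_nitrogen: int
    n_cycles_excluded_carbon: int
    n_cycles_excluded_nitrogen: int
    measurement: IsotopeMeasurement | None
    usable: bool


def _shift_with_mask(
    image_stack: np.ndarray, valid: np.ndarray, shift: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    dy, dx = shift
    rolled = np.roll(image_stack, (dy, dx), axis=(-2, -1))
    new_valid = np.roll(valid, (dy, dx), axis=(-2, -1)).copy()
    h, w = valid.shape[-2:]
    if dy > 0:
        new_valid[..., :dy, :] = False
    elif dy < 0:
        new_valid[..., dy:, :] = False
    if dx > 0:
        new_valid[..., :, :dx] = False
    elif dx < 0:
        new_valid[..., :, dx:] = False
    return rolled, new_valid


def align_cycles(
    stack: IonImageStack,
    reference_mass: str = "12C14N",
    max_shift: int = 10,
) -> tuple[IonImageStack, list[tuple[int, int]]]:
    """Register every cycle to cycle 0 by whole-pixel translation.

    For each cycle the drift (dy, dx) relative to cycle 0 is estimated by
    maximising the cross-correlation of its reference-mass image with
    cycle 0, searched within ``+-max_shift`` pixels; the negated drift is
    then applied identically to all four masses.  Returns the aligned
    stack and the per-cycle drifts.  Pixels rolled in from outside the
    frame are marked invalid.  Cycles whose reference image is all zero
    are left untouched with drift (0, 0).
    """
    if stack.n_cycles < 2:
        raise ValueError("alignment needs at least 2 cycles")
    ref_stack = stack.mass(reference_mass)
    ref = ref_stack[0].astype(float)
    h, w = stack.shape
    F_ref = np.fft.fft2(ref)

    # allowed wrap-around offsets |dy|,|dx| <= max_shift
    dy_idx = np.r_[0 : max_shift + 1, h - max_shift : h]
    dx_idx = np.r_[0 : max_shift + 1, w - max_shift : w]
    allowed = np.ix_(dy_idx, dx_idx)

    new_counts = stack.counts.astype(float).copy()
    new_valid = stack.valid_mask().copy()
    shifts: list[tuple[int, int]] = [(0, 0)]
    for c in range(1, stack.n_cycles):
        img = ref_stack[c].astype(float)
        if not np.any(img):
            shifts.append((0, 0))
            continue
        corr = np.fft.ifft2(F_ref * np.conj(np.fft.fft2(img))).real
        window = corr[allowed]
        peak = np.unravel_index(np.argmax(window), window.shape)
        dy = int(dy_idx[peak[0]])
        dx = int(dx_idx[peak[1]])
        dy = dy - h if dy > h // 2 else dy
        dx = dx - w if dx > w // 2 else dx
        # (dy, dx) is the correction that maps this cycle onto cycle 0;
        # the drift of the cycle itself is its negation.
        shifts.append((-dy, -dx))
        if (dy, dx) != (0, 0):
            rolled, cyc_valid = _shift_with_mask(
                new_counts[:, c], new_valid[c], (dy, dx)
            )
            new_counts[:, c] = rolled
            new_valid[c] = cyc_valid
    aligned = IonImageStack(
        counts=new_counts,
        pixel_size_nm=stack.pixel_size_nm,
        dwell_ms=stack.dwell_ms,
        valid=new_valid,
    )
    return aligned, shifts


def deadtime_correct(stack: IonImageStack, tau_ns: float = 44.0) -> IonImageStack:
    """Non-paralyzable dead-time correction, per pixel per cycle.

    With n counts in one dwell of length ``dwell_ms``, the corrected count
    is n / (1 - n * tau / dwell).  ``tau_ns = 0`` is a no-op.  Saturated
    pixels (n * tau / dwell >= 1) are set to NaN-free zero and marked
    invalid.
    """
    if tau_ns < 0:
        raise ValueError("tau_ns must be >= 0")
    if tau_ns == 0:
        return stack
    dwell_ns = stack.dwell_ms * 1e6
    loss = stack.counts * (tau_ns / dwell_ns)
    saturated = np.any(loss >= 1.0, axis=0)  # any mass saturates the pixel
    corrected = np.where(loss < 1.0, stack.counts / np.maximum(1.0 - loss, 1e-300), 0.0)
    valid = stack.valid_mask() & ~saturated
    return IonImageStack(
        counts=corrected,
        pixel_size_nm=stack.pixel_size_nm,
        dwell_ms=stack.dwell_ms,
        valid=valid,
    )


_CHANNELS = {
    "CN14": ("12C14N",),
    "CN_total": ("12C14N", "12C15N"),
}


def _threshold_value(image: np.ndarray, rule, k_mad: float) -> float:
    if rule is not None:
        return float(rule)
    med = float(np.median(image))
    mad = float(np.median(np.abs(image - med)))
    return med + k_mad * mad


def segment_particles(
    stack: IonImageStack,
    channel_spec: str = "CN14",
    min_diameter_um: float = 0.3,
    max_diameter_um: float | None = None,
    threshold: float | None = None,
    k_mad: float = 5.0,
    source: str = "auto_threshold",
) -> list[ROI]:
    """Automatic particle thresholding on the cycle-summed CN channel.

    The nitrogen-bearing CN- signal marks biomass against the N-free
    filter substrate.  Pixels above the threshold (explicit value, or
    background median + ``k_mad`` median absolute deviations) are grouped
    into 4-connected components; components with equivalent diameter
    outside [min, max] um are discarded.  ROIs are returned sorted by
    area descending, ties broken by top-left pixel.
    """
    if channel_spec not in _CHANNELS:
        raise ValueError(f"channel_spec must be one of {sorted(_CHANNELS)}")
    image = stack.cycle_summed(_CHANNELS[channel_spec])
    if not np.any(image):
        return []
    thresh = _threshold_value(image, threshold, k_mad)
    binary = image > thresh
    labels = measure.label(binary, connectivity=1)
    px_um = stack.pixel_size_nm / 1000.0
    rois: list[ROI] = []
    for region in measure.regionprops(labels):
        diameter = region.equivalent_diameter_area * px_um
        if diameter < min_diameter_um:
            continue
        if max_diameter_um is not None and diameter > max_diameter_um:
            continue
        pixels = frozenset(map(tuple, region.coords))
        rois.append(
            ROI(
                id=f"roi_{len(rois)}",
                pixels=pixels,
                source=source,
                area_um2=region.area * px_um**2,
            )
        )
    rois.sort(key=lambda r: (-r.n_pixels, min(r.pixels)))
    return [replace(r, id=f"{source}_{i}") for i, r in enumerate(rois)]


def find_hotspots(
    stack: IonImageStack,
    min_diameter_um: float = 4.0,
    max_diameter_um: float = 50.0,
    threshold: float | None = None,
    k_mad: float = 10.0,
) -> list[ROI]:
    """Find protist-scale hotspots of high CN- signal (4-50 um band).

    Same pipeline as :func:`segment_particles` with a wider size band and
    a more conservative default threshold; intended for shallow scans over
    large (possibly stitched) filter areas.
    """
    return segment_particles(
        stack,
        channel_spec="CN14",
        min_diameter_um=min_diameter_um,
        max_diameter_um=max_diameter_um,
        threshold=threshold,
        k_mad=k_mad,
        source="hotspot",
    )


def _ratio_by_cycle(
    num: np.ndarray, den: np.ndarray, valid: np.ndarray, rows: np.ndarray, cols: np.ndarray
) -> np.ndarray:
    num_roi = np.where(valid[:, rows, cols], num[:, rows, cols], 0.0)
    den_roi = np.where(valid[:, rows, cols], den[:, rows, cols], 0.0)
    num_sum = num_roi.sum(axis=1)
    den_sum = den_roi.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den_sum > 0, num_sum / np.maximum(den_sum, 1e-300), np.nan)


def _mean_sem(ratios: np.ndarray) -> tuple[float, float, int]:
    used = ratios[np.isfinite(ratios)]
    n = used.size
    if n == 0:
        return float("nan"), float("nan"), 0
    mean = float(np.mean(used))
    sem = float(np.std(used, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return mean, sem, n


def roi_isotope_stats(
    stack: IonImageStack,
    roi: ROI,
    constants: IsotopeConstants | None = None,
) -> ROIIsotopeRecord:
    """Ratio-by-cycle mean/SEM for one ROI plus derived isotope values.

    For each cycle the carbon ratio is sum(13C12C)/sum(12C2) over the ROI
    pixels and the nitrogen ratio sum(12C15N)/sum(12C14N); atom fractions,
    APE and X_net come from the across-cycle mean ratios.
    """
    h, w = stack.shape
    rows, cols = roi.indices()
    if rows.min() < 0 or rows.max() >= h or cols.min() < 0 or cols.max() >= w:
        raise ValueError(f"ROI {roi.id} extends outside the {h}x{w} image")
    valid = stack.valid_mask()
    c_ratios = _ratio_by_cycle(stack.mass("13C12C"), stack.mass("12C2"), valid, rows, cols)
    n_ratios = _ratio_by_cycle(stack.mass("12C15N"), stack.mass("12C14N"), valid, rows, cols)
    c_mean, c_sem, c_n = _mean_sem(c_ratios)
    n_mean, n_sem, n_n = _mean_sem(n_ratios)
    usable = c_n > 0 or n_n > 0
    measurement = None
    if c_n > 0 and n_n > 0:
        measurement = IsotopeMeasurement.from_ion_ratios(c_mean, n_mean, constants)
    return ROIIsotopeRecord(
        roi_id=roi.id,
        carbon_ratios=c_ratios,
        nitrogen_ratios=n_ratios,
        carbon_ratio_mean=c_mean,
        carbon_ratio_sem=c_sem,
        nitrogen_ratio_mean=n_mean,
        nitrogen_ratio_sem=n_sem,
        n_cycles_used_carbon=c_n,
        n_cycles_used_nitrogen=n_n,
        n_cycles_excluded_carbon=stack.n_cycles - c_n,
        n_cycles_excluded_nitrogen=stack.n_cycles - n_n,
        measurement=measurement,
        usable=usable,
    )


def write_roi_records_csv(records: Iterable[ROIIsotopeRecord], path) -> None:
    """Write ROI isotope records as CSV (one row per usable ROI)."""
    import pandas as pd

    rows = []
    for rec in records:
        m = rec.measurement
        rows.append(
            {
                "roi_id": rec.roi_id,
                "carbon_ratio_mean": rec.carbon_ratio_mean,
                "carbon_ratio_sem": rec.carbon_ratio_sem,
                "nitrogen_ratio_mean": rec.nitrogen_ratio_mean,
                "nitrogen_ratio_sem": rec.nitrogen_ratio_sem,
                "n_cycles_used_carbon": rec.n_cycles_used_carbon,
                "n_cycles_used_nitrogen": rec.n_cycles_used_nitrogen,
                "f13C": m.f13C if m else float("nan"),
                "f15N": m.f15N if m else float("nan"),
                "ape13C": m.ape13C if m else float("nan"),
                "ape15N": m.ape15N if m else float("nan"),
                "c_net": m.c_net if m else float("nan"),
                "n_net": m.n_net if m else float("nan"),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
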