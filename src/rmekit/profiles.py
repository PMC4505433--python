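"""Line-scan extraction and the relative membrane expression (RME) statistic.

A line profile is a set of bilinearly interpolated intensity samples along a
segment that fully crosses one cell. From each profile the two plasma-membrane
crossings are located as intensity peaks near the cell boundary, and

    RME = 100 * (M - C) / I_max

where M is the average membrane fluorescence (mean of the two crossing peak
heights), C the average intracellular fluorescence (cell-span samples outside
the membrane segments, the nucleus, and optionally ER-colocalized regions) and
I_max the maximum fluorescence intensity of the profile within the cell span.
All three are background-subtracted first. A cell with protein evenly
distributed between membrane and intracellular compartments scores 0; a cell
with 100% of the protein at the membrane scores 100. Negative values
(intracellular excess) are reported as-is, never clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk

__all__ = [
    "LineProfile",
    "MembraneSegments",
    "RMEResult",
    "place_profiles",
    "sample_profile",
    "cell_span",
    "detect_membrane",
    "detect_membrane_bruteforce",
    "compute_rme",
    "er_mask_from_channel",
    "background_mode",
    "measure_scene_rme",
    "aggregate_rme",
]

SAMPLE_STEP_PX = 0.5
PERINUCLEAR_DILATION_PX = 2
BOUNDARY_EXTENSION = 0.2  # extend lines 20% of the chord beyond each boundary
# Samples at the very edge of the cell span average cell and background
# (partial pixel coverage + bilinear blending, together < 2 px); they belong
# to neither compartment and are excluded from the intracellular mean C.
EDGE_GUARD_SAMPLES = 4
# Sub-half-height membrane tails adjacent to a detected segment are partially
# membrane; exclude a 1 px margin around each segment from C as well.
SEGMENT_GUARD_SAMPLES = 2
FLAT_RTOL = 1e-9  # peak within this relative distance of baseline => flat


@dataclass
class LineProfile:
    """Intensity samples along a segment crossing a cell.

    ``positions`` are distances in µm from the first endpoint; ``endpoints``
    are (row, col) pixel coordinates (0-based, pixel-centred).
    """

    endpoints: tuple[tuple[float, float], tuple[float, float]]
    positions: np.ndarray
    intensities: np.ndarray
    cell_id: int = 0
    profile_id: int = 0

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Row/col coordinates of every sample."""
        (r0, c0), (r1, c1) = self.endpoints
        n = len(self.positions)
        t = np.linspace(0.0, 1.0, n)
        return r0 + t * (r1 - r0), c0 + t * (c1 - c0)


@dataclass
class MembraneSegments:
    """Membrane crossings of one profile: entry/exit index intervals."""

    entry: tuple[int, int]  # half-open [start, stop) indices into the profile
    exit: tuple[int, int]
    peak_heights: tuple[float, float]
    baseline: float
    flat: bool = False  # no peak above the intracellular baseline


@dataclass
class RMEResult:
    rme: float
    M: float
    C: float
    I_max: float
    profile_id: int = 0
    cell_id: int = 0
    flags: tuple[str, ...] = ()


def _line_hits_mask(
    mask: np.ndarray, p0: np.ndarray, p1: np.ndarray, step: float = 0.25
) -> bool:
    n = max(int(np.hypot(*(p1 - p0)) / step), 2)
    t = np.linspace(0.0, 1.0, n)
    rr = np.clip(np.rint(p0[0] + t * (p1[0] - p0[0])).astype(int), 0, mask.shape[0] - 1)
    cc = np.clip(np.rint(p0[1] + t * (p1[1] - p0[1])).astype(int), 0, mask.shape[1] - 1)
    return bool(mask[rr, cc].any())


def _chord_through_mask(mask, center, angle, offset):
    """Entry/exit points of the chord at ``angle`` (radians, from the col
    axis), shifted ``offset`` px perpendicular from ``center``. Returns
    (p_in, p_out) or None if the chord misses the mask."""
    d = np.array([math.sin(angle), math.cos(angle)])
    perp = np.array([-math.cos(angle), math.sin(angle)])
    base = np.asarray(center, dtype=float) + offset * perp
    diag = math.hypot(*mask.shape)
    s = np.arange(-diag, diag, 0.25)
    rr = base[0] + s * d[0]
    cc = base[1] + s * d[1]
    ok = (rr >= 0) & (rr <= mask.shape[0] - 1) & (cc >= 0) & (cc <= mask.shape[1] - 1)
    inside = np.zeros_like(s, dtype=bool)
    ri = np.rint(rr[ok]).astype(int)
    ci = np.rint(cc[ok]).astype(int)
    inside[ok] = mask[ri, ci]
    if not inside.any():
        return None
    idx = np.nonzero(inside)[0]
    s_in, s_out = s[idx[0]], s[idx[-1]]
    return base, d, s_in, s_out


def place_profiles(
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray | None = None,
    n_lines: int = 3,
    min_chord_frac: float = 0.8,
) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Choose deterministic line-scan endpoints for one cell.

    Lines aim through the cell centroid at ``n_lines`` evenly spread angles
    (0°, 180°/n, ...). A candidate that intersects the nucleus dilated by 2 px
    (the perinuclear region) is shifted perpendicular to its axis in whole-
    pixel steps until clear; if no admissible chord exists at that angle the
    angle is advanced in 5° steps (a deterministic sweep, never random). Each
    returned line is extended 20% of the chord length beyond the cell boundary
    on both sides.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if not cell_mask.any():
        raise ValueError("empty cell mask")
    center = ndimage.center_of_mass(cell_mask)
    area = float(cell_mask.sum())
    r_eq = math.sqrt(area / math.pi)
    avoid = None
    if nucleus_mask is not None and nucleus_mask.any():
        avoid = dilation(nucleus_mask, disk(PERINUCLEAR_DILATION_PX))

    max_offset = int(0.6 * r_eq)
    endpoints = []
    for i in range(n_lines):
        base_angle = math.radians(i * 180.0 / n_lines)
        found = None
        for sweep in range(36):  # up to 180° in 5° steps
            angle = base_angle + math.radians(5.0 * sweep)
            for mag in range(0, max_offset + 1):
                for offset in ([0] if mag == 0 else [mag, -mag]):
                    chord = _chord_through_mask(cell_mask, center, angle, offset)
                    if chord is None:
                        continue
                    base, d, s_in, s_out = chord
                    if (s_out - s_in) < min_chord_frac * r_eq:
                        continue
                    p_in = base + s_in * d
                    p_out = base + s_out * d
                    if avoid is not None and _line_hits_mask(avoid, p_in, p_out):
                        continue
                    ext = BOUNDARY_EXTENSION * (s_out - s_in)
                    p0 = base + (s_in - ext) * d
                    p1 = base + (s_out + ext) * d
                    h, w = cell_mask.shape
                    p0 = np.clip(p0, [0, 0], [h - 1, w - 1])
                    p1 = np.clip(p1, [0, 0], [h - 1, w - 1])
                    found = (tuple(p0), tuple(p1))
                    break
                if found:
                    break
            if found:
                break
        if found is None:
            raise ValueError(
                f"no admissible line placement for cell at centroid {center}"
            )
        endpoints.append(found)
    return endpoints


def sample_profile(
    image: np.ndarray,
    endpoints: tuple[tuple[float, float], tuple[float, float]],
    pixel_size: float = 1.0,
    cell_id: int = 0,
    profile_id: int = 0,
) -> LineProfile:
    """Bilinearly interpolate the image along a segment at 0.5-pixel steps."""
    p0 = np.asarray(endpoints[0], dtype=float)
    p1 = np.asarray(endpoints[1], dtype=float)
    length = float(np.hypot(*(p1 - p0)))
    if length == 0:
        raise ValueError("profile endpoints are identical")
    # endpoint-inclusive sampling at a step of at most 0.5 px
    n = int(math.ceil(length / SAMPLE_STEP_PX)) + 1
    t = np.linspace(0.0, 1.0, n)
    rr = p0[0] + t * (p1[0] - p0[0])
    cc = p0[1] + t * (p1[1] - p0[1])
    vals = ndimage.map_coordinates(
        np.asarray(image, dtype=np.float64), [rr, cc], order=1, mode="nearest"
    )
    positions = t * length * pixel_size
    return LineProfile(
        endpoints=(tuple(p0), tuple(p1)), positions=positions,
        intensities=vals, cell_id=cell_id, profile_id=profile_id,
    )


def _samples_in_mask(profile: LineProfile, mask: np.ndarray) -> np.ndarray:
    rr, cc = profile.coords()
    ri = np.clip(np.rint(rr).astype(int), 0, mask.shape[0] - 1)
    ci = np.clip(np.rint(cc).astype(int), 0, mask.shape[1] - 1)
    return mask[ri, ci]


def cell_span(profile: LineProfile, cell_mask: np.ndarray) -> tuple[int, int]:
    """Half-open index interval of the (longest) run of samples inside the cell."""
    inside = _samples_in_mask(profile, cell_mask)
    if not inside.any():
        raise ValueError("profile does not cross the cell mask")
    # longest contiguous run
    best, cur, start, best_start = 0, 0, 0, 0
    for i, v in enumerate(inside):
        if v:
            if cur == 0:
                start = i
            cur += 1
            if cur > best:
                best, best_start = cur, start
        else:
            cur = 0
    return best_start, best_start + best


def _segment_around(region: np.ndarray, peak_idx: int, thr: float) -> tuple[int, int]:
    lo = peak_idx
    while lo > 0 and region[lo - 1] >= thr:
        lo -= 1
    hi = peak_idx + 1
    while hi < len(region) and region[hi] >= thr:
        hi += 1
    return lo, hi


def _refine_peak(region: np.ndarray, idx: int) -> float:
    """Parabolic refinement of a peak height sampled at discrete steps.

    The crest of a membrane crossing is ~1 px wide, so the highest 0.5-px
    sample can undershoot the true peak; the vertex of the parabola through
    the peak sample and its neighbours recovers it.
    """
    v = float(region[idx])
    if idx <= 0 or idx >= len(region) - 1:
        return v
    a, b, c = float(region[idx - 1]), v, float(region[idx + 1])
    denom = a - 2 * b + c
    if denom >= 0:  # not locally concave; keep the sample value
        return v
    h = b - 0.125 * (a - c) ** 2 / denom
    return max(v, h)


def detect_membrane(
    profile: LineProfile, span: tuple[int, int]
) -> MembraneSegments:
    """Locate the two membrane crossings of a profile.

    The entry (exit) peak is the highest sample within the outer 25% of the
    cell span at that end; its membrane segment is the contiguous run of
    samples at or above half height over the intracellular baseline (median of
    the central 50% of the span). A profile with no peak above baseline (an
    evenly filled cell) is flagged ``flat``: each segment degenerates to the
    single boundary sample and M falls back to the baseline, driving RME to 0.
    """
    lo, hi = span
    n = hi - lo
    if n < 8:
        raise ValueError("cell span shorter than 8 samples")
    region = np.asarray(profile.intensities[lo:hi], dtype=float)
    k = max(2, int(math.ceil(0.25 * n)))
    q = n // 4
    central = region[q: n - q] if n - 2 * q >= 1 else region
    baseline = float(np.median(central))

    e_idx = int(np.argmax(region[:k]))
    x_idx = n - k + int(np.argmax(region[n - k:]))
    pe, px_ = float(region[e_idx]), float(region[x_idx])

    tol = FLAT_RTOL * max(abs(baseline), abs(pe), abs(px_), 1.0)
    if max(pe, px_) - baseline <= tol:
        return MembraneSegments(
            entry=(lo, lo + 1), exit=(hi - 1, hi),
            peak_heights=(baseline, baseline), baseline=baseline, flat=True,
        )

    thr_e = baseline + 0.5 * (pe - baseline)
    thr_x = baseline + 0.5 * (px_ - baseline)
    pe = _refine_peak(region, e_idx)
    px_ = _refine_peak(region, x_idx)
    e_lo, e_hi = _segment_around(region, e_idx, thr_e)
    x_lo, x_hi = _segment_around(region, x_idx, thr_x)
    if e_hi > x_lo:  # keep the two segments disjoint
        mid = (e_idx + x_idx) // 2 + 1
        e_hi = min(e_hi, mid)
        x_lo = max(x_lo, mid)
        x_lo = min(x_lo, x_idx)
        e_hi = max(e_hi, e_idx + 1)
    return MembraneSegments(
        entry=(lo + e_lo, lo + e_hi), exit=(lo + x_lo, lo + x_hi),
        peak_heights=(pe, px_), baseline=baseline, flat=False,
    )


def detect_membrane_bruteforce(
    profile: LineProfile, span: tuple[int, int]
) -> MembraneSegments:
    """Naive reference implementation of :func:`detect_membrane`.

    Scans every sample of each outer window for the maximum and grows each
    half-height segment sample by sample. Used as an independent oracle in the
    test suite for short profiles; must agree with the vectorized rule.
    """
    lo, hi = span
    n = hi - lo
    if n < 8:
        raise ValueError("cell span shorter than 8 samples")
    region = [float(v) for v in profile.intensities[lo:hi]]
    k = max(2, int(math.ceil(0.25 * n)))
    q = n // 4
    central = sorted(region[q: n - q] if n - 2 * q >= 1 else region)
    m = len(central)
    baseline = (
        central[m // 2] if m % 2 == 1 else 0.5 * (central[m // 2 - 1] + central[m // 2])
    )
    e_idx, pe = 0, region[0]
    for i in range(k):
        if region[i] > pe:
            e_idx, pe = i, region[i]
    x_idx, px_ = n - k, region[n - k]
    for i in range(n - k, n):
        if region[i] > px_:
            x_idx, px_ = i, region[i]
    tol = FLAT_RTOL * max(abs(baseline), abs(pe), abs(px_), 1.0)
    if max(pe, px_) - baseline <= tol:
        return MembraneSegments(
            entry=(lo, lo + 1), exit=(hi - 1, hi),
            peak_heights=(baseline, baseline), baseline=baseline, flat=True,
        )
    out = []
    peaks = []
    for idx, pk in ((e_idx, pe), (x_idx, px_)):
        thr = baseline + 0.5 * (pk - baseline)
        a = idx
        while a > 0 and region[a - 1] >= thr:
            a -= 1
        b = idx + 1
        while b < n and region[b] >= thr:
            b += 1
        out.append((a, b))
        if 0 < idx < n - 1:
            u, v, w_ = region[idx - 1], region[idx], region[idx + 1]
            den = u - 2 * v + w_
            if den < 0:
                pk = max(pk, v - 0.125 * (u - w_) ** 2 / den)
        peaks.append(pk)
    pe, px_ = peaks
    (e_lo, e_hi), (x_lo, x_hi) = out
    if e_hi > x_lo:
        mid = (e_idx + x_idx) // 2 + 1
        e_hi = min(e_hi, mid)
        x_lo = max(x_lo, mid)
        x_lo = min(x_lo, x_idx)
        e_hi = max(e_hi, e_idx + 1)
    return MembraneSegments(
        entry=(lo + e_lo, lo + e_hi), exit=(lo + x_lo, lo + x_hi),
        peak_heights=(pe, px_), baseline=baseline, flat=False,
    )


def compute_rme(
    profile: LineProfile,
    segments: MembraneSegments,
    span: tuple[int, int],
    nucleus_samples: np.ndarray | None = None,
    er_samples: np.ndarray | None = None,
    background: float = 0.0,
    er_affects_max: bool = False,
) -> RMEResult:
    """Compute RME = 100 * (M - C) / I_max for one profile.

    ``nucleus_samples``/``er_samples`` are boolean per-sample arrays; samples
    inside either are excluded from the intracellular average C (ER exclusion
    implements the ER-colocalized-signal correction). The image background is
    subtracted from M, C and I_max before the ratio. I_max is the per-profile
    maximum within the cell span (so a fully membrane-localized cell scores
    100 regardless of brightness). RME may be negative and is not clamped.
    """
    lo, hi = span
    vals = np.asarray(profile.intensities, dtype=float) - background
    idx = np.arange(lo, hi)
    g = 0 if segments.flat else SEGMENT_GUARD_SAMPLES
    in_segment = (
        (idx >= segments.entry[0] - g) & (idx < segments.entry[1] + g)
    ) | ((idx >= segments.exit[0] - g) & (idx < segments.exit[1] + g))
    exclude = in_segment.copy()
    # span-edge samples blend cell and background; keep them out of C
    exclude[:EDGE_GUARD_SAMPLES] = True
    exclude[len(exclude) - EDGE_GUARD_SAMPLES:] = True
    flags: list[str] = []
    if nucleus_samples is not None:
        exclude |= np.asarray(nucleus_samples[lo:hi], dtype=bool)
    if er_samples is not None:
        er = np.asarray(er_samples[lo:hi], dtype=bool)
        if (~(er | exclude)).sum() == 0:
            raise ValueError("ER exclusion removed every intracellular sample")
        exclude |= er

    intra = vals[lo:hi][~exclude]
    if intra.size == 0:
        raise ValueError("no intracellular samples available for C")
    C = float(intra.mean())

    if segments.flat:
        M = segments.baseline - background
        flags.append("flat")
    else:
        M = float(np.mean(segments.peak_heights)) - background

    span_vals = vals[lo:hi]
    if er_samples is not None and er_affects_max:
        keep = ~np.asarray(er_samples[lo:hi], dtype=bool)
        span_vals = span_vals[keep] if keep.any() else span_vals
    I_max = float(span_vals.max())
    if not segments.flat:
        # the refined crest height is part of the profile's maximum
        I_max = max(I_max, float(np.max(segments.peak_heights)) - background)
    if I_max <= 0:
        raise ValueError("I_max <= 0 after background subtraction (empty cell)")
    rme = 100.0 * (M - C) / I_max
    if rme < 0:
        flags.append("negative")
    return RMEResult(
        rme=rme, M=M, C=C, I_max=I_max,
        profile_id=profile.profile_id, cell_id=profile.cell_id,
        flags=tuple(flags),
    )


def er_mask_from_channel(
    er_channel: np.ndarray, cell_mask: np.ndarray
) -> np.ndarray:
    """Otsu threshold of the ER-marker channel restricted to the cell mask."""
    vals = np.asarray(er_channel, dtype=float)[cell_mask]
    if vals.size == 0 or np.ptp(vals) == 0:
        return np.zeros_like(cell_mask)
    thr = threshold_otsu(vals)
    return cell_mask & (er_channel > thr)


def background_mode(image: np.ndarray, outside_mask: np.ndarray) -> float:
    """Mode of the intensity histogram outside all cell masks."""
    vals = np.asarray(image, dtype=float)[outside_mask]
    if vals.size == 0:
        return 0.0
    if np.ptp(vals) == 0:
        return float(vals[0])
    hist, edges = np.histogram(vals, bins=256)
    i = int(np.argmax(hist))
    return float(0.5 * (edges[i] + edges[i + 1]))


def measure_scene_rme(
    scene,
    n_lines: int = 3,
    er_exclusion: bool = False,
    er_affects_max: bool = False,
    channel: str = "protein",
) -> pd.DataFrame:
    """Run the full profile pipeline on a synthetic scene (truth masks).

    Measures every transfected cell: line placement, sampling, membrane
    detection and RME, returning one row per profile with columns
    cell_id, profile_id, M, C, I_max, rme, flags.
    """
    image = scene.channels[channel]
    outside = ~np.any([t.cell for t in scene.truth], axis=0)
    bg = background_mode(image, outside)
    rows = []
    pid = 0
    for cid, t in enumerate(scene.truth):
        if not t.spec.transfected:
            continue
        er_mask = None
        if er_exclusion:
            er_mask = er_mask_from_channel(scene.channels["er_marker"], t.cell)
        eps = place_profiles(t.cell, t.nucleus, n_lines=n_lines)
        for ep in eps:
            prof = sample_profile(
                image, ep, pixel_size=scene.spec.pixel_size,
                cell_id=cid, profile_id=pid,
            )
            span = cell_span(prof, t.cell)
            segs = detect_membrane(prof, span)
            nuc = _samples_in_mask(prof, t.nucleus)
            er = _samples_in_mask(prof, er_mask) if er_mask is not None else None
            res = compute_rme(
                prof, segs, span, nucleus_samples=nuc, er_samples=er,
                background=bg, er_affects_max=er_affects_max,
            )
            rows.append(
                dict(
                    cell_id=cid, profile_id=pid, M=res.M, C=res.C,
                    I_max=res.I_max, rme=res.rme, flags=",".join(res.flags),
                )
            )
            pid += 1
    return pd.DataFrame(rows)


def aggregate_rme(per_profile: pd.DataFrame) -> dict:
    """Hierarchical condition summary: profile -> cell -> repeat -> condition.

    ``per_profile`` needs columns ``rme`` and ``cell_id``; an optional
    ``repeat`` column adds the experimental-repeat level (without it a single
    repeat is assumed). The mean is the unweighted mean of repeat means (each
    repeat mean the unweighted mean of its cell means), and the SEM is
    computed across repeats with n = number of repeats; with fewer than two
    repeats the SEM is undefined and flagged.
    """
    df = per_profile.copy()
    if "repeat" not in df.columns:
        df["repeat"] = 1
    cell_means = (
        df.groupby(["repeat", "cell_id"])["rme"].mean().rename("cell_mean")
    )
    repeat_means = cell_means.groupby("repeat").mean()
    n = len(repeat_means)
    mean = float(repeat_means.mean())
    if n >= 2:
        sem = float(repeat_means.std(ddof=1) / math.sqrt(n))
        flag = ""
    else:
        sem = float("nan")
        flag = "sem-undefined: fewer than 2 repeats"
    return dict(
        mean=mean, sem=sem, n_repeats=n,
        repeat_means=repeat_means.to_dict(),
        cell_means=cell_means.reset_index().to_dict("records"),
        flag=flag,
    )
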