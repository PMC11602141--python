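"""Supercoiled-condensate classification and population statistics.

A molecule is called a "supercoiled condensate" when a tracked DNA feature
(1) keeps its apparent moving-window diffusion constant below 10 kb^2/s
for at least 200 consecutive frames, (2) carries colocalized ParB signal,
and (3) marks a local high-density DNA spot. Population summaries include
the condensed fraction with an exact (Clopper-Pearson) binomial 95% CI,
plectoneme size-versus-position probability maps, and ParB-plectoneme
colocalization distances against a circularly-permuted null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .dynamics import moving_window_D
from .preprocess import Kymograph, estimate_background
from .tracking import Track

__all__ = [
    "CondensateCall",
    "classify_condensate",
    "condensed_fraction",
    "size_position_map",
    "coloc_distance",
]


@dataclass
class CondensateCall:
    """Per-molecule condensation call with its supporting evidence."""

    molecule_id: str | int
    condensed: bool
    onset_frame: int | None = None
    pin_position_kb: float | None = None
    evidence: dict = field(default_factory=dict)


def _qualifying_run(ok: np.ndarray, missing: np.ndarray, min_frames: int,
                    max_gap: int) -> tuple[int, int] | None:
    """First index run with >= min_frames where ``ok`` holds, allowing up to
    ``max_gap`` consecutive missing frames inside; a non-missing failure
    breaks the run."""
    n = ok.size
    start = None
    gap = 0
    for i in range(n):
        if ok[i]:
            if start is None:
                start = i
            gap = 0
        elif missing[i] and start is not None:
            gap += 1
            if gap > max_gap:
                if i - gap - start + 1 >= min_frames:
                    return start, i - gap + 1
                start, gap = None, 0
        else:
            if start is not None and i - gap - start >= min_frames:
                return start, i - gap
            start, gap = None, 0
    if start is not None and n - gap - start >= min_frames:
        return start, n - gap
    return None


def classify_condensate(
    dna_tracks: list[Track],
    dna_kymo: Kymograph,
    parb_kymo: Kymograph | None,
    molecule_id: str | int = 0,
    D_thresh_kb2s: float = 10.0,
    min_frames: int = 200,
    coloc_radius_px: int = 7,
    max_gap_frames: int = 5,
    parb_enrichment: float = 2.0,
    dna_enrichment: float = 1.5,
    window_frames: int = 11,
) -> CondensateCall:
    """Screen one molecule's sized DNA tracks for a supercoiled condensate.

    Condensed iff some track sustains moving-window D < ``D_thresh_kb2s``
    for >= ``min_frames`` frames (<= ``max_gap_frames`` missing frames
    tolerated inside the run), with time-averaged ParB intensity within
    ``coloc_radius_px`` of the track exceeding ``parb_enrichment`` times
    the molecule-wide ParB level, and with the track's DNA fraction at
    least ``dna_enrichment`` times the molecule's typical window fraction.
    Without a ParB channel the call is negative with the flag unset.
    """
    dt = dna_kymo.frame_interval_s
    parb_bg = estimate_background(parb_kymo) if parb_kymo is not None else 0.0
    best = None
    for track in dna_tracks:
        if track.n_frames < min_frames:
            continue
        birth, dense_px = track.dense_positions()
        pos_kb = (dense_px - dna_kymo.end_pixels[0]) * dna_kymo.kb_per_pixel
        d_series = moving_window_D(pos_kb, dt, window_frames=window_frames)
        ok = d_series < D_thresh_kb2s
        missing = np.isnan(d_series)
        run = _qualifying_run(ok, missing, min_frames, max_gap_frames)
        if run is None:
            continue
        lo, hi = run
        frames = np.arange(birth + lo, birth + hi)
        px_run = dense_px[lo:hi]

        coloc_flag = None
        if parb_kymo is not None:
            left, right = parb_kymo.end_pixels
            width = 2 * coloc_radius_px + 1
            local = []
            for f, p in zip(frames, px_run):
                if np.isnan(p) or f >= parb_kymo.n_frames:
                    continue
                c = int(round(p))
                a = max(left, c - coloc_radius_px)
                b = min(right, c + coloc_radius_px) + 1
                local.append(np.sum(parb_kymo.intensity[f, a:b] - parb_bg))
            span = parb_kymo.intensity[:, parb_kymo.span] - parb_bg
            molecule_level = float(np.mean(span)) * width
            local_mean = float(np.mean(local)) if local else 0.0
            coloc_flag = bool(local_mean >= parb_enrichment * max(molecule_level, 1e-12))

        fr = np.array([o.fraction for o in track.observations], dtype=float)
        track_fraction = float(np.nanmean(fr)) if np.any(~np.isnan(fr)) else np.nan
        typical = _typical_window_fraction(dna_kymo)
        dna_flag = bool(np.isfinite(track_fraction)
                        and track_fraction >= dna_enrichment * typical)

        min_d = float(np.nanmin(d_series[lo:hi]))
        evidence = dict(min_window_D_kb2s=min_d,
                        sustained_frames=int(hi - lo),
                        parb_colocalized=coloc_flag,
                        dna_enriched=dna_flag,
                        track_fraction=track_fraction,
                        typical_window_fraction=typical)
        if coloc_flag and dna_flag:
            valid = ~np.isnan(px_run)
            pin_kb = float(np.median(pos_kb[lo:hi][valid[:hi - lo]])) if valid.any() else None
            return CondensateCall(molecule_id, True, onset_frame=int(frames[0]),
                                  pin_position_kb=pin_kb, evidence=evidence)
        best = evidence
    return CondensateCall(molecule_id, False, evidence=best or {})


def _typical_window_fraction(kymo: Kymograph, half_width_px: int = 2) -> float:
    """Median fraction of molecule intensity inside a generic +/-2 px window."""
    bg = estimate_background(kymo)
    span = kymo.intensity[:, kymo.span] - bg
    totals = span.sum(axis=1, keepdims=True)
    totals[totals <= 0] = np.nan
    w = 2 * half_width_px + 1
    kernel = np.ones(w)
    rolled = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="valid"), 1, span)
    fractions = rolled / totals
    return float(np.nanmedian(fractions))


def condensed_fraction(n_condensed: int, n_total: int,
                       alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Condensed-molecule fraction with an exact binomial confidence interval.

    Returns ``(k/n, (lower, upper))`` using the Clopper-Pearson method.
    """
    if n_total < 1:
        raise ValueError("need at least one molecule")
    if not (0 <= n_condensed <= n_total):
        raise ValueError("invalid counts")
    lo, hi = proportion_confint(n_condensed, n_total, alpha=alpha, method="beta")
    return n_condensed / n_total, (float(lo), float(hi))


def size_position_map(
    tracks: list[Track],
    kymo: Kymograph,
    dna_length_kb: float,
    n_pos_bins: int = 20,
    n_size_bins: int = 20,
    size_range_kb: tuple[float, float] | None = None,
):
    """Joint probability map of feature size versus relative DNA position.

    Histograms every sized observation of every track over (relative
    position, size_kb) and normalises the matrix to sum to 1. Returns
    ``(prob_matrix, pos_edges, size_edges)``.
    """
    pos, size = [], []
    for t in tracks:
        kb = t.positions_kb(kymo)
        for o, p in zip(t.observations, kb):
            if o.size_kb is not None:
                pos.append(p / dna_length_kb)
                size.append(o.size_kb)
    pos = np.asarray(pos)
    size = np.asarray(size)
    if size_range_kb is None:
        size_range_kb = (0.0, dna_length_kb)
    H, pe, se = np.histogram2d(pos, size, bins=[n_pos_bins, n_size_bins],
                               range=[(0.0, 1.0), size_range_kb])
    total = H.sum()
    if total > 0:
        H = H / total
    return H, pe, se


def coloc_distance(
    parb_tracks: list[Track],
    plectoneme_tracks: list[Track],
    kymo: Kymograph,
    coloc_radius_kb: float = 2.66,
    n_permutations: int = 200,
    rng: np.random.Generator | None = None,
):
    """Nearest ParB-to-plectoneme distances per frame, with a shuffled null.

    For every frame where both channels have a feature, records the
    distance (kb) from each ParB track position to the nearest plectoneme.
    The null distribution circularly permutes the plectoneme position
    series in time, destroying any frame-wise correlation while preserving
    each channel's marginal dynamics. Returns ``(distances_kb, summary)``
    where summary holds the median distance, the fraction within
    ``coloc_radius_kb`` and the permuted-null means of both.
    """
    if rng is None:
        rng = np.random.default_rng(0)

    def per_frame_positions(tracks):
        out: dict[int, list[float]] = {}
        for t in tracks:
            kb = t.positions_kb(kymo)
            for o, p in zip(t.observations, kb):
                out.setdefault(o.frame, []).append(float(p))
        return out

    parb_pos = per_frame_positions(parb_tracks)
    plect_pos = per_frame_positions(plectoneme_tracks)
    frames = sorted(set(parb_pos) & set(plect_pos))
    if not frames:
        return np.array([]), dict(median_kb=np.nan, frac_within=np.nan,
                                  null_median_kb=np.nan, null_frac_within=np.nan)

    def distances(parb_map, plect_map, frame_list):
        d = []
        for f in frame_list:
            plect = np.asarray(plect_map[f])
            for p in parb_map[f]:
                d.append(float(np.min(np.abs(plect - p))))
        return np.asarray(d)

    dists = distances(parb_pos, plect_pos, frames)
    summary = dict(median_kb=float(np.median(dists)),
                   frac_within=float(np.mean(dists <= coloc_radius_kb)))

    null_medians, null_fracs = [], []
    frame_arr = np.asarray(frames)
    for _ in range(n_permutations):
        shift = int(rng.integers(1, len(frames))) if len(frames) > 1 else 0
        shifted = {int(f): plect_pos[int(g)]
                   for f, g in zip(frame_arr, np.roll(frame_arr, shift))}
        nd = distances(parb_pos, shifted, frames)
        null_medians.append(np.median(nd))
        null_fracs.append(np.mean(nd <= coloc_radius_kb))
    summary["null_median_kb"] = float(np.mean(null_medians))
    summary["null_frac_within"] = float(np.mean(null_fracs))
    return dists, summary
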