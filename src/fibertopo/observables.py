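"""Experiment-facing observables of fiber conformations and ensembles.

* fragment-length distributions (FLD): for every pair of base pairs
  separated by n along the chain, the probability of correlated breaks
  falls exponentially with their 3-D distance, FLD(n) = <exp(-d/lambda)>
  with lambda = 4.0 nm — the radioprobing break-correlation model;
* internucleosome contact statistics: close contacts binned by neighbor
  offset, the stacked fraction, and nucleosome flip-out events;
* sedimentation coefficients via the Kirkwood double-sum approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .geometry import FiberConformation

#: exponential drop constant of the break-correlation weight (nm)
DEFAULT_LAMBDA_NM = 4.0
#: core-center distance defining a close contact (nm): one core diameter
CONTACT_CUTOFF_NM = 11.0
#: |cos| threshold on superhelical-axis alignment for a stacked pair
STACKING_COS_MIN = 0.7
#: flip-out criterion: radial excursion beyond this multiple of the
#: snapshot's median core distance from the local fiber axis
FLIPOUT_FACTOR = 1.5

#: standard mononucleosome sedimentation coefficient (S) and effective
#: hydrodynamic radius (nm) for the Kirkwood treatment
S_MONO_DEFAULT = 11.1
R_EFF_DEFAULT = 5.5


@dataclass
class FLDProfile:
    """Fragment-length distribution: n (nt) -> mean break-correlation
    weight.  1 nt is identified with 1 bp of chain separation."""

    lambda_nm: float
    n_values: np.ndarray     # (m,) integer fragment lengths
    values: np.ndarray       # (m,) mean weights

    def __post_init__(self):
        self.n_values = np.asarray(self.n_values, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("FLD values must be non-negative")
        if np.any(np.diff(self.n_values) != 1):
            raise ValueError("FLD must cover a contiguous range of n")

    def value_at(self, n: int) -> float:
        idx = int(n) - int(self.n_values[0])
        if idx < 0 or idx >= len(self.values):
            raise KeyError(f"fragment length {n} outside profile range")
        return float(self.values[idx])

    @property
    def range(self) -> tuple[int, int]:
        return int(self.n_values[0]), int(self.n_values[-1])


def fld_profile(conformations, lambda_nm: float = DEFAULT_LAMBDA_NM,
                n_range: tuple[int, int] = (250, 400)) -> FLDProfile:
    """FLD(n) = mean over base-pair pairs (i, i+n), and over
    conformations, of exp(-d(i, i+n)/lambda).

    ``conformations`` — one FiberConformation (or bare (N, 3) coordinate
    array) or a list of them sharing a common bp count.  Fragment lengths
    exceeding the chain length are absent from the profile, not zero.
    """
    if lambda_nm <= 0:
        raise ValueError("lambda must be positive")
    if isinstance(conformations, (FiberConformation, np.ndarray)):
        conformations = [conformations]
    coords = []
    for c in conformations:
        pts = c.bp_origins() if isinstance(c, FiberConformation) else np.asarray(c, float)
        coords.append(pts)
    nbp = {len(p) for p in coords}
    if len(nbp) != 1:
        raise ValueError("conformations must share the same bp count")
    nbp = nbp.pop()
    n_lo, n_hi = int(n_range[0]), int(n_range[1])
    n_hi = min(n_hi, nbp - 1)
    if n_hi < n_lo:
        raise ValueError("no valid fragment lengths in range")
    ns = np.arange(n_lo, n_hi + 1)
    vals = np.zeros(len(ns))
    for pts in coords:
        for k, n in enumerate(ns):
            d = np.linalg.norm(pts[n:] - pts[:-n], axis=1)
            vals[k] += np.exp(-d / lambda_nm).mean()
    vals /= len(coords)
    return FLDProfile(lambda_nm=lambda_nm, n_values=ns, values=vals)


def detect_peaks(profile: FLDProfile, min_prominence: float = 0.05,
                 smooth_window: int = 5):
    """Local maxima of a smoothed FLD profile.

    The profile is smoothed with a centered ``smooth_window``-nt moving
    average; peaks must have prominence of at least ``min_prominence``
    times the profile's dynamic range.  Returns a list of
    (position nt, height, prominence) sorted by position.
    """
    y = profile.values
    if len(y) == 0:
        return []
    w = max(1, int(smooth_window))
    kernel = np.ones(w) / w
    pad = w // 2
    ypad = np.pad(y, pad, mode="edge")
    ys = np.convolve(ypad, kernel, mode="valid")[:len(y)]
    rng = ys.max() - ys.min()
    if rng <= 0:
        return []
    idx, props = find_peaks(ys, prominence=min_prominence * rng)
    out = [(int(profile.n_values[i]), float(ys[i]), float(p))
           for i, p in zip(idx, props["prominences"])]
    return sorted(out)


@dataclass
class ContactStats:
    """Internucleosome contact statistics of a snapshot or ensemble."""

    counts_by_offset: dict = field(default_factory=dict)  # {1: .., 2: .., 3: .., "4+": ..}
    stacking_fraction: float = 0.0
    flipout_rate: float = 0.0
    n_snapshots: int = 1

    def contact_fraction(self, offset) -> float:
        total = sum(self.counts_by_offset.values())
        if total == 0:
            return 0.0
        return self.counts_by_offset.get(offset, 0) / total


def _is_stacked_pair(ci, ai, cj, aj, stacking_distance, stacking_width):
    dd = cj - ci
    d = float(np.linalg.norm(dd))
    if d >= CONTACT_CUTOFF_NM:
        return False
    dot = float(ai @ aj)
    if abs(dot) <= STACKING_COS_MIN:
        return False
    m = ai + np.sign(dot if dot != 0 else 1.0) * aj
    nm = np.linalg.norm(m)
    if nm < 1e-12:
        return False
    ax = abs(float(dd @ (m / nm)))
    return ax < stacking_distance + 3.0 * stacking_width


def _local_axis_radii(centers: np.ndarray, window: int = 5) -> np.ndarray:
    """Distance of each core from the local fiber axis.

    The axis near core i is the least-squares line through the sliding
    ``window``-nucleosome centroids whose windows contain i (a line fit
    smooths out the two-start wobble of the raw centroid polyline)."""
    n = len(centers)
    if n < window + 1:
        mu = centers.mean(axis=0)
        d = centers - mu
        u = np.linalg.svd(d, full_matrices=False)[2][0]
        return np.linalg.norm(d - np.outer(d @ u, u), axis=1)
    cents = np.array([centers[i:i + window].mean(axis=0)
                      for i in range(n - window + 1)])
    radii = np.empty(n)
    for i in range(n):
        lo = max(0, min(i - window + 1, len(cents) - window))
        seg = cents[lo:lo + window]
        mu = seg.mean(axis=0)
        u = np.linalg.svd(seg - mu, full_matrices=False)[2][0]
        d = centers[i] - mu
        radii[i] = np.linalg.norm(d - (d @ u) * u)
    return radii


def classify_contacts(snapshots, cutoff: float = CONTACT_CUTOFF_NM,
                      stacking_distance: float = 5.7,
                      stacking_width: float = 0.5) -> ContactStats:
    """Close contacts binned by neighbor offset, stacked fraction and
    flip-out rate.

    ``snapshots`` — (centers, axes) arrays of shape (n, 3), a
    FiberConformation, or a list of either.  A pair is a close contact if
    the core centers are within ``cutoff``; stacked if additionally the
    superhelical axes align (|cos| > 0.7) and the face-to-face (axial)
    separation is inside the stacking well; flipped out if a core sits
    more than 1.5x the snapshot's median radial distance from the local
    fiber axis.
    """
    if isinstance(snapshots, FiberConformation) or (
            isinstance(snapshots, tuple) and len(snapshots) == 2):
        snapshots = [snapshots]
    counts = {1: 0, 2: 0, 3: 0, "4+": 0}
    stacked_sum = 0.0
    flip_sum = 0.0
    nsnap = 0
    for snap in snapshots:
        if isinstance(snap, FiberConformation):
            centers, axes = snap.core_centers_axes()
        else:
            centers, axes = snap
        centers = np.asarray(centers, float)
        axes = np.asarray(axes, float)
        n = len(centers)
        if n < 4:
            nsnap += 1
            continue
        stacked = np.zeros(n, bool)
        for i in range(n):
            for j in range(i + 1, n):
                d = float(np.linalg.norm(centers[j] - centers[i]))
                if d >= cutoff:
                    continue
                off = j - i
                counts[off if off <= 3 else "4+"] += 1
                if _is_stacked_pair(centers[i], axes[i], centers[j], axes[j],
                                    stacking_distance, stacking_width):
                    stacked[i] = stacked[j] = True
        stacked_sum += stacked.mean()
        radii = _local_axis_radii(centers)
        med = np.median(radii)
        if med > 1e-9:
            flip_sum += float(np.mean(radii > FLIPOUT_FACTOR * med))
        nsnap += 1
    return ContactStats(counts_by_offset=counts,
                        stacking_fraction=stacked_sum / max(nsnap, 1),
                        flipout_rate=flip_sum / max(nsnap, 1),
                        n_snapshots=nsnap)


def stacking_fraction(ensemble, stacking_distance: float = 5.7,
                      stacking_width: float = 0.5) -> float:
    """Mean over post-burn-in snapshots of the fraction of nucleosomes
    with at least one stacked partner."""
    cs, axs = ensemble.centers_axes()
    fr = []
    for s in range(len(cs)):
        centers, axes = cs[s], axs[s]
        n = len(centers)
        stacked = np.zeros(n, bool)
        for i in range(n):
            for j in range(i + 1, n):
                if _is_stacked_pair(centers[i], axes[i], centers[j], axes[j],
                                    stacking_distance, stacking_width):
                    stacked[i] = stacked[j] = True
        fr.append(stacked.mean())
    return float(np.mean(fr))


@dataclass
class SedimentationResult:
    s20w: float              # ensemble mean, Svedberg
    s_sd: float              # standard deviation across snapshots
    per_snapshot: np.ndarray

    def __post_init__(self):
        self.per_snapshot = np.asarray(self.per_snapshot, float)


def sedimentation(snapshots, s_mono: float = S_MONO_DEFAULT,
                  R_eff: float = R_EFF_DEFAULT) -> SedimentationResult:
    """Kirkwood double-sum sedimentation coefficient.

    s / s_mono = 1 + (2 R_eff / n) * sum_{i<j} 1/d_ij over core centers;
    a single nucleosome sediments at exactly s_mono.
    """
    if isinstance(snapshots, FiberConformation):
        snapshots = [snapshots]
    elif isinstance(snapshots, np.ndarray) and snapshots.ndim == 2:
        snapshots = [snapshots]
    vals = []
    for snap in snapshots:
        centers = snap.core_centers_axes()[0] if isinstance(snap, FiberConformation) \
            else np.asarray(snap, float)
        n = len(centers)
        acc = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                d = float(np.linalg.norm(centers[j] - centers[i]))
                if d < 1e-9:
                    raise ValueError("coincident core centers are degenerate")
                acc += 1.0 / d
        vals.append(s_mono * (1.0 + 2.0 * R_eff / n * acc))
    vals = np.asarray(vals)
    return SedimentationResult(s20w=float(vals.mean()),
                               s_sd=float(vals.std()),
                               per_snapshot=vals)


def ensemble_fld(ensemble, lambda_nm: float = DEFAULT_LAMBDA_NM,
                 n_range: tuple[int, int] = (250, 400),
                 max_snapshots: int = 60) -> FLDProfile:
    """FLD averaged over (a thinned subset of) post-burn-in snapshots."""
    snaps = ensemble.snapshots()
    if len(snaps) > max_snapshots:
        idx = np.linspace(0, len(snaps) - 1, max_snapshots).astype(int)
        snaps = [snaps[i] for i in idx]
    return fld_profile(snaps, lambda_nm=lambda_nm, n_range=n_range)
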