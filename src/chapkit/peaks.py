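"""Kernel-convolution peak calling.

The caller mirrors a bespoke ChAP-Seq detection scheme for bacterial
genomes:

1. *Width estimation* — provisional peaks are all maximal runs of coverage
   above 3x the genome-wide mean; each run's FWHM (distance between the
   outermost positions still at or above half the run maximum) is measured,
   and the median FWHM becomes the expected peak width ``w``.
2. *Kernel* — the negated second derivative of a Gaussian density
   ("Mexican hat", positive center), truncated at 4 sigma with
   ``sigma = w/8`` so the kernel support spans the expected width, then
   mean-shifted so the weights sum to zero exactly (a constant track maps
   to an exactly-zero profile).
3. *Convolution* — circular (wrap-around) or zero-padded linear.
4. *Summit detection* — positions where the first difference of the
   convolution profile changes sign from positive to negative; plateaus
   report their center (rounded down); non-positive profile values are
   discarded.
5. *Scoring and filtering* — score = profile value at the summit
   (the convolution score), raw height = coverage at the summit; peaks with
   raw height below ``min_fold`` x mean coverage or non-positive score are
   dropped; overlapping extents keep only the higher-scoring summit.
6. *Normalization* — the background mass ``B`` = total coverage minus
   coverage inside all peak extents; ``norm_intensity = score / B * 1e6``,
   making intensities comparable across samples of different depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .coverage import CoverageTrack


class NoPeaksError(ValueError):
    """No position exceeds the detection threshold; carries the mean."""

    def __init__(self, mean_coverage: float, fold: float):
        self.mean_coverage = mean_coverage
        self.fold = fold
        super().__init__(
            f"no peaks detectable: no position exceeds "
            f"{fold} x mean coverage ({mean_coverage:.3f})")


class NormalizationError(ValueError):
    pass


class StageError(RuntimeError):
    """Peak-calling failure annotated with the stage that raised it."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"[{stage}] {original}")


@dataclass(frozen=True)
class Kernel:
    """Truncated, zero-sum, negated second-derivative-of-Gaussian weights."""

    sigma: float
    radius: int
    weights: np.ndarray  # indexed -radius..+radius

    def __post_init__(self):
        if len(self.weights) != 2 * self.radius + 1:
            raise ValueError("weights must span -radius..+radius")


@dataclass
class Peak:
    summit: int
    start: int
    end: int          # 0-based half-open extent; end may exceed L (wrap)
    raw_height: float
    score: float      # convolution value at the summit, arbitrary units
    norm_intensity: float | None = None
    sample: str = ""


@dataclass
class PeakSet:
    peaks: list
    expected_width: int
    mean_coverage: float
    norm_coefficient: float | None = None
    sample: str = ""
    condition: str = ""
    replicate: int = 0
    genome_length: int = 0

    def __len__(self) -> int:
        return len(self.peaks)

    def summits(self) -> np.ndarray:
        return np.array([p.summit for p in self.peaks], dtype=int)


# ---------------------------------------------------------------------------
# stage 1: expected width
# ---------------------------------------------------------------------------

def _above_runs(mask: np.ndarray, circular: bool) -> list:
    """Maximal runs of True as lists of absolute indices (a run crossing
    the origin of a circular genome is one run, indices beyond L)."""
    L = len(mask)
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, breaks + 1)
    if circular and len(runs) > 1 and idx[0] == 0 and idx[-1] == L - 1:
        runs[0] = np.concatenate([runs[-1], runs[0] + L]) - L  # keep order
        runs = runs[:-1]
    return [list(map(int, r)) for r in runs]


def peak_fwhm(values: np.ndarray, apex: int, circular: bool) -> int:
    """Full width at half maximum around ``apex``.

    The width is the distance between the outermost positions (walking
    left and right from the apex) whose coverage is still >= half the apex
    height, i.e. the positions just inside where coverage drops below half
    maximum.
    """
    v = values
    L = len(v)
    half = v[apex % L] / 2.0
    left = apex
    steps = 0
    while steps < L - 1 and v[(left - 1) % L] >= half:
        left -= 1
        steps += 1
        if not circular and left == 0:
            break
    right = apex
    steps = 0
    while steps < L - 1 and v[(right + 1) % L] >= half:
        right += 1
        steps += 1
        if not circular and right == L - 1:
            break
    return right - left


def estimate_expected_width(track: CoverageTrack, fold: float = 3.0) -> int:
    """Median FWHM over all provisional peaks (runs above fold x mean).

    The median of an even-length width list is the lower middle element,
    keeping the result a pure integer.
    """
    v = track.values
    mu = float(v.mean())
    mask = v > fold * mu
    runs = _above_runs(mask, track.circular)
    if not runs:
        raise NoPeaksError(mu, fold)
    widths = []
    L = len(v)
    for run in runs:
        apex = run[int(np.argmax([v[i % L] for i in run]))]
        widths.append(peak_fwhm(v, apex, track.circular))
    widths.sort()
    return int(widths[(len(widths) - 1) // 2])


# ---------------------------------------------------------------------------
# stage 2: kernel
# ---------------------------------------------------------------------------

def build_kernel(expected_width: int, sigma_ratio: float = 0.125) -> Kernel:
    """Negated second-derivative-of-Gaussian kernel.

    ``sigma = expected_width * sigma_ratio`` (default 1/8, so the 4-sigma
    truncation on both sides spans exactly the expected width); weights are
    mean-shifted to restore the analytic zero-sum broken by truncation.
    """
    if expected_width < 8:
        raise ValueError(f"expected width {expected_width} < 8 bp "
                         "(sigma would fall below 1)")
    sigma = float(expected_width) * sigma_ratio
    radius = math.ceil(4.0 * sigma)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-x ** 2 / (2.0 * sigma ** 2)) / (math.sqrt(2 * math.pi) * sigma)
    w = (sigma ** 2 - x ** 2) / sigma ** 4 * g  # -g''(x)
    w -= w.mean()
    return Kernel(sigma=sigma, radius=radius, weights=w)


# ---------------------------------------------------------------------------
# stage 3: convolution
# ---------------------------------------------------------------------------

def convolve(track: CoverageTrack, kernel: Kernel) -> np.ndarray:
    """profile[x] = sum_i weights[i] * values[(x - i) mod L] (circular)
    or with zero padding (linear)."""
    L = len(track)
    if kernel.radius >= L / 2:
        raise ValueError("kernel radius must be < genome length / 2")
    mode = "wrap" if track.circular else "constant"
    return ndimage.convolve1d(track.values, kernel.weights, mode=mode,
                              cval=0.0)


# ---------------------------------------------------------------------------
# stage 4: summit detection
# ---------------------------------------------------------------------------

def detect_summits(profile: np.ndarray, circular: bool = True) -> list:
    """Summit candidates where the first difference flips + -> -.

    A flat top (zero-run of the difference) reports its center position,
    rounded down. Candidates with non-positive profile value are dropped.
    """
    p = np.asarray(profile, dtype=np.float64)
    L = len(p)
    if circular:
        d = np.roll(p, -1) - p          # d[x] = p[(x+1) % L] - p[x]
    else:
        d = np.diff(p)
    s = np.sign(d)
    nz = np.flatnonzero(s)
    if len(nz) == 0:
        return []
    out = []
    n = len(nz)
    last = n if circular else n - 1
    for k in range(last):
        i = int(nz[k])
        j = int(nz[(k + 1) % n])
        if s[i] > 0 and s[j] < 0:
            m = (j - i) % L if circular else j - i
            pos = (i + (m + 1) // 2) % L
            if p[pos] > 0:
                out.append(pos)
    out.sort()
    return out


# ---------------------------------------------------------------------------
# stage 5: scoring and filtering
# ---------------------------------------------------------------------------

def score_filter(candidates: Sequence[int], profile: np.ndarray,
                 track: CoverageTrack, expected_width: int,
                 min_fold: float = 3.0, **set_kw) -> PeakSet:
    """Score candidates, apply the coverage filter, resolve overlaps.

    Keeps candidates whose raw summit coverage is >= ``min_fold`` x the
    genome-wide mean and whose convolution score is positive. The extent of
    a peak is summit +/- expected_width/2; where extents overlap only the
    higher-scoring summit survives.
    """
    L = len(track)
    mu = track.mean
    half = expected_width // 2
    kept = []
    for c in candidates:
        score = float(profile[c])
        raw = float(track.values[c])
        if raw >= min_fold * mu and score > 0:
            kept.append(Peak(summit=int(c), start=int(c) - half,
                             end=int(c) - half + expected_width,
                             raw_height=raw, score=score,
                             sample=set_kw.get("sample", track.sample)))
    # greedy overlap resolution: best score first, ties to smaller summit
    kept.sort(key=lambda p: (-p.score, p.summit))
    accepted = []
    for p in kept:
        clash = False
        for q in accepted:
            if _extents_overlap(p, q, L, track.circular):
                clash = True
                break
        if not clash:
            accepted.append(p)
    accepted.sort(key=lambda p: p.summit)
    set_kw.setdefault("sample", track.sample)
    set_kw.setdefault("condition", track.condition)
    set_kw.setdefault("replicate", track.replicate)
    return PeakSet(peaks=accepted, expected_width=int(expected_width),
                   mean_coverage=mu, genome_length=L, **set_kw)


def _extents_overlap(a: Peak, b: Peak, L: int, circular: bool) -> bool:
    if not circular:
        return a.start < b.end and b.start < a.end
    for shift in (-L, 0, L):
        if a.start + shift < b.end and b.start < a.end + shift:
            return True
    return False


# ---------------------------------------------------------------------------
# stage 6: inter-sample normalization
# ---------------------------------------------------------------------------

def normalize_peakset(peakset: PeakSet, track: CoverageTrack,
                      scale: float = 1e6) -> PeakSet:
    """Attach the normalization coefficient and normalized intensities.

    ``B`` = total genomic coverage minus the coverage inside all detected
    peak extents (the background mass); each peak's
    ``norm_intensity = score / B * scale``. Intensities are invariant under
    uniform rescaling of the track.
    """
    L = len(track)
    total = float(track.values.sum())
    in_peaks = np.zeros(L, dtype=bool)
    for p in peakset.peaks:
        idx = np.arange(p.start, p.end) % L
        in_peaks[idx] = True
    peak_mass = float(track.values[in_peaks].sum())
    B = total - peak_mass
    if B <= 0:
        raise NormalizationError(
            f"normalization coefficient must be positive (B={B:g}; peaks "
            "cover the whole genome?)")
    peaks = [replace(p, norm_intensity=p.score / B * scale)
             for p in peakset.peaks]
    return replace(peakset, peaks=peaks, norm_coefficient=B)


# ---------------------------------------------------------------------------
# full caller
# ---------------------------------------------------------------------------

def call_peaks(track: CoverageTrack, min_fold: float = 3.0,
               blacklist: Sequence[tuple] | None = None,
               sigma_ratio: float = 0.125,
               expected_width: int | None = None) -> PeakSet:
    """Run the full pipeline on one coverage track.

    ``blacklist`` is a list of (start, end) half-open intervals; peaks
    whose summit falls in one are removed before normalization (known
    artifact regions). ``expected_width`` overrides the estimator.
    Stage failures are re-raised as :class:`StageError` naming the stage.
    """
    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except (NoPeaksError, NormalizationError):
            raise
        except Exception as e:  # pragma: no cover - defensive
            raise StageError(name, e) from e

    if expected_width is None:
        expected_width = estimate_expected_width(track, fold=min_fold)
    kernel = _stage("build_kernel", build_kernel, expected_width,
                    sigma_ratio)
    profile = _stage("convolve", convolve, track, kernel)
    candidates = _stage("detect_summits", detect_summits, profile,
                        track.circular)
    peakset = _stage("score_filter", score_filter, candidates, profile,
                     track, expected_width, min_fold)
    if blacklist:
        keep = [p for p in peakset.peaks
                if not any(s <= p.summit < e for s, e in blacklist)]
        peakset = replace(peakset, peaks=keep)
    return _stage("normalize_peakset", normalize_peakset, peakset, track)


# ---------------------------------------------------------------------------
# peak table I/O
# ---------------------------------------------------------------------------

def write_peaks(peakset: PeakSet, path, chrom: str = "chr") -> None:
    """BED6+4: chrom start end name score(norm_intensity) strand summit
    raw_height conv_score norm_coefficient-in-header."""
    L = peakset.genome_length or None
    with open(path, "w") as fh:
        fh.write(f"#norm_coefficient={peakset.norm_coefficient}\t"
                 f"expected_width={peakset.expected_width}\t"
                 f"mean_coverage={peakset.mean_coverage:g}\t"
                 f"sample={peakset.sample}\tcondition={peakset.condition}\t"
                 f"replicate={peakset.replicate}\t"
                 f"genome_length={peakset.genome_length}\n")
        for i, p in enumerate(peakset.peaks, 1):
            s = p.start % L if L else max(p.start, 0)
            e = p.end % L if (L and p.end > L) else p.end
            ni = "" if p.norm_intensity is None else f"{p.norm_intensity:.6g}"
            fh.write(f"{chrom}\t{s}\t{e}\tpeak_{i}\t{ni}\t.\t{p.summit}\t"
                     f"{p.raw_height:g}\t{p.score:.6g}\n")


def read_peaks(path) -> PeakSet:
    meta = {}
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                for kv in line[1:].split("\t"):
                    k, _, v = kv.partition("=")
                    meta[k] = v
                continue
            if not line:
                continue
            f = line.split("\t")
            peaks.append(Peak(summit=int(f[6]), start=int(f[1]),
                              end=int(f[2]), raw_height=float(f[7]),
                              score=float(f[8]),
                              norm_intensity=float(f[4]) if f[4] else None,
                              sample=meta.get("sample", "")))
    B = meta.get("norm_coefficient", "None")
    return PeakSet(peaks=peaks,
                   expected_width=int(meta.get("expected_width", 0)),
                   mean_coverage=float(meta.get("mean_coverage", 0)),
                   norm_coefficient=None if B == "None" else float(B),
                   sample=meta.get("sample", ""),
                   condition=meta.get("condition", ""),
                   replicate=int(meta.get("replicate", 0)),
                   genome_length=int(meta.get("genome_length", 0)))
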