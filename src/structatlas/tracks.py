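"""Windowed sequence tracks: stacking energy, position preference, curvature,
GC skew and AT content.

Property tracks are computed at single-base step by default; reduction to
pixel resolution is the renderer's job, which keeps tracks independent of
the figure width. Windows containing N contribute only their valid
positions to the mean; a window with no valid positions is NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .scales import CurvatureModel, PropertyScale, encode, load_builtin_scale, lookup_profile
from .seqio import SequenceRecord


@dataclass(frozen=True)
class WindowSpec:
    """A sliding window: ``window`` bp wide, advanced ``step`` bp at a time."""

    window: int
    step: int = 1

    def __post_init__(self):
        if self.window < 1 or self.step < 1:
            raise ValueError("window and step must be >= 1")


@dataclass(frozen=True)
class Track:
    """Values sampled along a sequence at window centers.

    Value i sits at coordinate ``start_offset + i * step`` (bp); for
    window-centered tracks ``start_offset == floor(window / 2)``.
    """

    name: str
    values: np.ndarray
    window: int
    step: int = 1
    start_offset: int = field(default=-1)
    units: str = ""

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.start_offset < 0:
            object.__setattr__(self, "start_offset", self.window // 2)

    @property
    def positions(self) -> np.ndarray:
        return self.start_offset + np.arange(len(self.values)) * self.step

    def __len__(self) -> int:
        return len(self.values)


def expected_count(length: int, window: int, step: int) -> int:
    return (length - window) // step + 1


def windowed_mean(profile: np.ndarray, spec: WindowSpec, name: str = "",
                  units: str = "", extra_offset: int = 0) -> Track:
    """Running mean over the profile, ignoring NaN entries per window."""
    profile = np.asarray(profile, dtype=float)
    if spec.window > len(profile):
        raise ValueError("window exceeds sequence")
    win = np.lib.stride_tricks.sliding_window_view(profile, spec.window)[::spec.step]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        vals = np.nanmean(win, axis=1)
    return Track(name=name, values=vals, window=spec.window, step=spec.step,
                 start_offset=spec.window // 2 + extra_offset, units=units)


def default_window(plotted_length: int) -> int:
    """Default property-track window: 0.1% of the plotted length, min 1 bp."""
    return max(1, round(0.001 * plotted_length))


def _resolve_spec(seq: SequenceRecord, spec: WindowSpec | None) -> WindowSpec:
    return spec if spec is not None else WindowSpec(default_window(seq.length))


def stacking_energy_track(seq: SequenceRecord, spec: WindowSpec | None = None,
                          scale: PropertyScale | None = None) -> Track:
    """Mean dinucleotide stacking energy per window (kcal/mol).

    Values are negative; the smallest magnitudes mark DNA that melts most
    easily.
    """
    scale = scale or load_builtin_scale("stacking_energy")
    spec = _resolve_spec(seq, spec)
    prof = lookup_profile(seq, scale)
    t = windowed_mean(prof, spec, name="stacking_energy", units=scale.units)
    return t


def position_preference_track(seq: SequenceRecord, spec: WindowSpec | None = None,
                              scale: PropertyScale | None = None) -> Track:
    """Mean trinucleotide nucleosome position preference per window.

    Low values indicate decreased preference for nucleosome wrapping,
    i.e. potentially open chromatin.
    """
    scale = scale or load_builtin_scale("position_preference")
    spec = _resolve_spec(seq, spec)
    prof = lookup_profile(seq, scale)
    return windowed_mean(prof, spec, name="position_preference", units=scale.units)


def curvature_profile(seq: SequenceRecord, model: CurvatureModel) -> np.ndarray:
    """Per-window intrinsic curvature magnitude from the wedge model.

    Each dinucleotide step contributes a wedge vector whose in-plane angle
    advances with the cumulative helical twist; the profile value is the
    magnitude of the vector sum over ``model.window_len`` consecutive steps,
    divided by the number of steps (degrees/step, >= 0). Windows touching N
    are NaN.
    """
    codes = encode(seq)
    m = model.window_len
    if m > len(codes):
        raise ValueError("window exceeds sequence")
    kmers = sorted(model.wedge)
    wedge = np.zeros(17)
    direc = np.zeros(17)
    twist = np.zeros(17)
    for kmer in kmers:
        i = codes_of(kmer)
        wedge[i] = model.wedge[kmer]
        direc[i] = model.direction[kmer]
        twist[i] = model.twist[kmer]
    valid = codes < 4
    step_valid = valid[:-1] & valid[1:]
    idx = np.where(step_valid, codes[:-1].astype(np.int64) * 4 + codes[1:], 16)
    w = wedge[idx]
    d = np.deg2rad(direc[idx])
    tw = np.deg2rad(twist[idx])
    phase = np.concatenate(([0.0], np.cumsum(tw)[:-1]))
    vec = w * np.exp(1j * (phase + d))
    vec[~step_valid] = np.nan + 0j
    n_steps = m - 1  # m bp span -> m-1 dinucleotide steps
    kernel = np.ones(n_steps)
    summed = np.convolve(vec, kernel, mode="valid")
    mag = np.abs(summed) / n_steps
    return mag


def codes_of(kmer: str) -> int:
    code = 0
    for c in kmer:
        code = code * 4 + "ACGT".index(c)
    return code


def curvature_track(seq: SequenceRecord, model: CurvatureModel | None = None,
                    spec: WindowSpec | None = None) -> Track:
    """Smoothed intrinsic-curvature magnitude track (degrees/step, >= 0)."""
    model = model or load_builtin_scale("curvature")
    spec = _resolve_spec(seq, spec)
    prof = curvature_profile(seq, model)
    return windowed_mean(prof, spec, name="curvature", units="deg/step",
                         extra_offset=model.window_len // 2)


def _window_counts(mask: np.ndarray, window: int, step: int) -> np.ndarray:
    csum = np.concatenate(([0], np.cumsum(mask)))
    starts = np.arange(0, len(mask) - window + 1, step)
    return csum[starts + window] - csum[starts]


def gc_skew_track(seq: SequenceRecord, spec: WindowSpec | None = None,
                  per_window_length: bool = False) -> Track:
    """GC skew per window: (#G - #C) / (#G + #C), in [-1, 1].

    The denominator is the G+C count (the standard skew definition); pass
    ``per_window_length=True`` to normalise by window length instead.
    Windows with no G or C are NaN. Default window: 10,000 bp.
    """
    spec = spec or WindowSpec(min(10000, seq.length))
    if spec.window > seq.length:
        raise ValueError("window exceeds sequence")
    codes = encode(seq)
    g = _window_counts(codes == 2, spec.window, spec.step).astype(float)
    c = _window_counts(codes == 1, spec.window, spec.step).astype(float)
    denom = np.full_like(g, float(spec.window)) if per_window_length else g + c
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(denom > 0, (g - c) / np.where(denom > 0, denom, 1), np.nan)
    return Track(name="gc_skew", values=vals, window=spec.window, step=spec.step,
                 units="(G-C)/(G+C)")


def at_content_track(seq: SequenceRecord, spec: WindowSpec | None = None) -> Track:
    """Fraction of A+T per window, in [0, 1].

    The denominator is the window length, so N-containing windows dilute the
    fraction rather than becoming NaN. Default window: 0.1% of the sequence
    (the plotted region when called by the renderer), minimum 1 bp.
    """
    spec = _resolve_spec(seq, spec)
    if spec.window > seq.length:
        raise ValueError("window exceeds sequence")
    codes = encode(seq)
    at = _window_counts((codes == 0) | (codes == 3), spec.window, spec.step)
    vals = at / float(spec.window)
    return Track(name="at_content", values=vals, window=spec.window,
                 step=spec.step, units="fraction")


def gc_content_track(seq: SequenceRecord, spec: WindowSpec | None = None) -> Track:
    """Fraction of G+C per window (companion to at_content_track)."""
    spec = _resolve_spec(seq, spec)
    if spec.window > seq.length:
        raise ValueError("window exceeds sequence")
    codes = encode(seq)
    gc = _window_counts((codes == 1) | (codes == 2), spec.window, spec.step)
    return Track(name="gc_content", values=gc / float(spec.window),
                 window=spec.window, step=spec.step, units="fraction")
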