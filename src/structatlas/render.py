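"""Atlas rendering: fixed-width multi-lane rasters of structural tracks.

Each lane reduces one track to ``width_px`` pixels (mean of the track
values whose centers fall in each pixel's bp span), normalises it to [0, 1]
(mean +/- k*SD by default, saturating at k standard deviations; fixed 0-9
for repeat bins) and paints it through a three-point colormap. Lanes are
stacked over a strand-separated gene lane and a bp scale bar. A sidecar
JSON records per-lane mean/SD/window/step and the bp-per-pixel resolution
so every figure is reproducible from its own metadata.

Rendering is deterministic: fixed DPI, fixed fonts, no timestamps.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib.colors import LinearSegmentedColormap
from matplotlib.figure import Figure
from matplotlib.patches import Rectangle

from . import repeats as repeats_mod
from . import tracks as tracks_mod
from .seqio import GeneFeature, SequenceRecord
from .tracks import Track, WindowSpec, default_window

logger = logging.getLogger(__name__)

DPI = 100
LANE_PX = 28
GENE_PX = 44
SCALE_PX = 38
TITLE_PX = 24


@dataclass(frozen=True)
class LaneSpec:
    """How one track becomes one color lane."""

    track: str
    colors: tuple[str, str, str]  # low, mid, high
    scaling: str = "mean_sd"      # or "fixed"
    fixed_range: tuple[float, float] = (0.0, 1.0)
    saturation_k: float = 3.0
    invert: bool = False
    label: str = ""

    def __post_init__(self):
        if self.saturation_k <= 0:
            raise ValueError("saturation_k must be > 0")
        if not self.label:
            object.__setattr__(self, "label", self.track)


@dataclass
class AtlasSpec:
    """Declarative description of one atlas figure."""

    lanes: list[LaneSpec]
    width_px: int = 2500
    region: tuple[int, int] | None = None
    annotations: list[GeneFeature] = field(default_factory=list)
    title: str = ""
    fmt: str = "png"
    shade_introns: bool = False  # light intron shading (zoom style)

    def __post_init__(self):
        if self.width_px < 1:
            raise ValueError("width_px must be >= 1")


def resolution(region_length: int, width_px: int) -> float:
    """Base pairs represented by one pixel: region_length / width_px."""
    if region_length < 1 or width_px < 1:
        raise ValueError("region_length and width_px must be >= 1")
    return region_length / width_px


def downsample(track: Track, region: tuple[int, int], width_px: int) -> np.ndarray:
    """Per-pixel mean of track values whose centers fall in each pixel span.

    Pixels containing no finite value are NaN (rendered as background).
    """
    start, end = region
    length = end - start
    bpp = length / width_px
    pos = track.positions
    vals = track.values
    keep = (pos >= start) & (pos < end) & np.isfinite(vals)
    pix = np.minimum(((pos[keep] - start) / bpp).astype(int), width_px - 1)
    sums = np.bincount(pix, weights=vals[keep], minlength=width_px)
    counts = np.bincount(pix, minlength=width_px)
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return out


def color_scale(pixels: np.ndarray, lane: LaneSpec, mu: float, sigma: float
                ) -> np.ndarray:
    """Normalise pixel values to [0, 1] for the lane's colormap.

    mean_sd: mu maps to 0.5 and the scale saturates (clamps) at
    mu +/- saturation_k * sigma. With sigma == 0 everything is 0.5.
    fixed: linear between the lane's fixed_range, clamped.
    NaN passes through.
    """
    pixels = np.asarray(pixels, dtype=float)
    if lane.scaling == "mean_sd":
        if sigma < 0:
            raise ValueError("sigma must be >= 0")
        if sigma == 0:
            out = np.where(np.isnan(pixels), np.nan, 0.5)
        else:
            out = 0.5 + (pixels - mu) / (2 * lane.saturation_k * sigma)
    elif lane.scaling == "fixed":
        lo, hi = lane.fixed_range
        out = (pixels - lo) / (hi - lo)
    else:
        raise ValueError(f"unknown scaling {lane.scaling!r}")
    out = np.clip(out, 0.0, 1.0)
    if lane.invert:
        out = 1.0 - out
    return out


def _cmap(lane: LaneSpec) -> LinearSegmentedColormap:
    cmap = LinearSegmentedColormap.from_list(lane.track, list(lane.colors))
    cmap.set_bad("#ffffff")
    return cmap


# ---------------------------------------------------------------------------
# Default lane sets (colors follow the figure conventions: red = melts
# easily, green = open chromatin, blue = direct repeats, red = inverted
# repeats, turquoise/magenta = GC skew, red = AT rich, blue = curved)

def default_lane_specs() -> list[LaneSpec]:
    """Whole-locus lane order: stacking, position preference, direct and
    inverted repeats, GC skew, AT content (genes are drawn separately)."""
    return [
        LaneSpec("stacking_energy", ("#00009f", "#f2f2f2", "#bf0000"),
                 label="stacking energy"),
        LaneSpec("position_preference", ("#008f00", "#f2f2f2", "#4d4d4d"),
                 label="position preference"),
        LaneSpec("direct_repeats", ("#ffffff", "#8c8cff", "#00009f"),
                 scaling="fixed", fixed_range=(0.0, 9.0), label="direct repeats"),
        LaneSpec("inverted_repeats", ("#ffffff", "#ff8c8c", "#9f0000"),
                 scaling="fixed", fixed_range=(0.0, 9.0), label="inverted repeats"),
        LaneSpec("gc_skew", ("#bf00bf", "#f7f7f7", "#00afaf"), label="GC skew"),
        LaneSpec("at_content", ("#00009f", "#f2f2f2", "#bf0000"),
                 label="AT content"),
    ]


def zoom_lane_specs() -> list[LaneSpec]:
    """Zoom lane order: GC skew dropped, intrinsic curvature added on top."""
    return [
        LaneSpec("curvature", ("#ffffff", "#8c8cff", "#00004d"),
                 label="curvature"),
        *[spec for spec in default_lane_specs() if spec.track != "gc_skew"],
    ]


# ---------------------------------------------------------------------------
# Track computation helpers shared by CLI, zoom and the acceptance script

def compute_atlas_tracks(seq: SequenceRecord, *, window: int | None = None,
                         step: int | None = None, gc_window: int = 10000,
                         repeat_window: int = repeats_mod.DEFAULT_WINDOW,
                         repeat_step: int | None = None,
                         approximate_repeats: bool = False) -> dict[str, Track]:
    """All whole-locus lanes for one sequence."""
    w = window or default_window(seq.length)
    spec = WindowSpec(w, step or 1)
    return {
        "stacking_energy": tracks_mod.stacking_energy_track(seq, spec),
        "position_preference": tracks_mod.position_preference_track(seq, spec),
        "direct_repeats": repeats_mod.repeat_track(
            seq, window=repeat_window, step=repeat_step, strand="direct",
            approximate=approximate_repeats),
        "inverted_repeats": repeats_mod.repeat_track(
            seq, window=repeat_window, step=repeat_step, strand="inverted",
            approximate=approximate_repeats),
        "gc_skew": tracks_mod.gc_skew_track(
            seq, WindowSpec(min(gc_window, seq.length), step or 1)),
        "at_content": tracks_mod.at_content_track(seq, spec),
    }


def compute_zoom_tracks(seq: SequenceRecord, *, window: int | None = None,
                        repeat_window: int = repeats_mod.DEFAULT_WINDOW,
                        approximate_repeats: bool = False) -> dict[str, Track]:
    """Zoom lanes for an (already oriented) region sequence.

    The AT-content and property windows default to 0.1% of the region
    length; repeat lanes scan the displayed region.
    """
    w = window or default_window(seq.length)
    spec = WindowSpec(w, 1)
    rep_w = min(repeat_window, max(2, seq.length // 4))
    return {
        "curvature": tracks_mod.curvature_track(seq, spec=spec),
        "stacking_energy": tracks_mod.stacking_energy_track(seq, spec),
        "position_preference": tracks_mod.position_preference_track(seq, spec),
        "direct_repeats": repeats_mod.repeat_track(
            seq, window=rep_w, strand="direct",
            approximate=approximate_repeats),
        "inverted_repeats": repeats_mod.repeat_track(
            seq, window=rep_w, strand="inverted",
            approximate=approximate_repeats),
        "at_content": tracks_mod.at_content_track(seq, spec),
    }


# ---------------------------------------------------------------------------
# Figure composition

def _format_bp(x: float) -> str:
    if x >= 1_000_000:
        return f"{x / 1_000_000:.2f} Mbp"
    if x >= 1_000:
        return f"{x / 1_000:.1f} kbp"
    return f"{int(x)} bp"


def _draw_gene_lane(ax, features: list[GeneFeature], region: tuple[int, int],
                    shade_introns: bool) -> None:
    start, end = region
    ax.set_xlim(start, end)
    ax.set_ylim(0, 2)
    ax.axhline(1.0, color="#cccccc", lw=0.6)
    for f in features:
        if f.end <= start or f.start >= end:
            continue
        y0 = 1.12 if f.strand == "+" else 0.12
        color = "#b22222" if f.strand == "+" else "#1f5fbf"
        if shade_introns:
            for s, e in f.introns:
                ax.add_patch(Rectangle((s, y0), e - s, 0.76, facecolor=color,
                                       alpha=0.30, edgecolor="none"))
            for s, e in f.exons:
                ax.add_patch(Rectangle((s, y0), e - s, 0.76, facecolor=color,
                                       edgecolor="none"))
        else:
            ax.add_patch(Rectangle((f.start, y0), f.end - f.start, 0.76,
                                   facecolor=color, edgecolor="none"))
        mid = (max(f.start, start) + min(f.end, end)) / 2
        ax.text(mid, y0 + 0.38, f.gene_id, ha="center", va="center",
                fontsize=6, color="white", clip_on=True)
    ax.text(start, 1.5, " + strand", fontsize=6, ha="left", va="center",
            color="#666666")
    ax.text(start, 0.5, " - strand", fontsize=6, ha="left", va="center",
            color="#666666")
    ax.set_axis_off()


def render_atlas(seq: SequenceRecord, spec: AtlasSpec,
                 tracks: dict[str, Track], out_path: str | Path,
                 extra_sidecar: dict | None = None) -> dict:
    """Render a multi-lane atlas; returns (and writes) the sidecar dict.

    The sidecar JSON is written next to the image (same stem, ``.json``).
    """
    out_path = Path(out_path)
    region = spec.region or (0, seq.length)
    start, end = region
    if not (0 <= start < end <= seq.length):
        raise ValueError(f"region {region} outside sequence of length {seq.length}")
    for lane in spec.lanes:
        if lane.track not in tracks:
            raise ValueError(f"missing track for lane {lane.track!r}")

    width_px = spec.width_px
    res = resolution(end - start, width_px)
    n_lanes = len(spec.lanes)
    total_px = TITLE_PX + n_lanes * LANE_PX + GENE_PX + SCALE_PX
    fig = Figure(figsize=(width_px / DPI, total_px / DPI), dpi=DPI)

    sidecar: dict = {
        "sequence": seq.id,
        "region": [start, end],
        "width_px": width_px,
        "resolution_bp_per_px": res,
        "lanes": {},
    }

    def add_row(top_px: int, height_px: int):
        bottom = 1 - (top_px + height_px) / total_px
        return fig.add_axes((0.0, bottom, 1.0, height_px / total_px))

    y = 0
    if spec.title or True:
        ax = add_row(y, TITLE_PX)
        ax.set_axis_off()
        ax.text(0.001, 0.5, spec.title or seq.id, fontsize=8, va="center",
                transform=ax.transAxes)
        ax.text(0.999, 0.5, f"resolution: {res:g} bp/pixel", fontsize=7,
                va="center", ha="right", transform=ax.transAxes)
        y += TITLE_PX

    for lane in spec.lanes:
        track = tracks[lane.track]
        pixels = downsample(track, region, width_px)
        mu = float(np.nanmean(track.values)) if np.any(np.isfinite(track.values)) else 0.0
        sigma = float(np.nanstd(track.values)) if np.any(np.isfinite(track.values)) else 0.0
        norm = color_scale(pixels, lane, mu, sigma)
        ax = add_row(y, LANE_PX)
        ax.imshow(np.ma.masked_invalid(norm)[None, :], cmap=_cmap(lane),
                  aspect="auto", vmin=0.0, vmax=1.0, interpolation="nearest")
        ax.set_axis_off()
        ax.text(0.002, 0.5, f"{lane.label} [{track.units}]", fontsize=6,
                va="center", transform=ax.transAxes,
                bbox=dict(facecolor="white", alpha=0.6, edgecolor="none",
                          pad=0.8))
        sidecar["lanes"][lane.track] = {
            "mean": mu, "sd": sigma,
            "window": track.window, "step": track.step,
        }
        y += LANE_PX

    ax = add_row(y, GENE_PX)
    _draw_gene_lane(ax, spec.annotations, region, spec.shade_introns)
    y += GENE_PX

    ax = add_row(y, SCALE_PX)
    ax.set_xlim(start, end)
    ax.set_ylim(0, 1)
    ax.spines[["left", "right", "bottom"]].set_visible(False)
    ax.spines["top"].set_visible(True)
    ax.get_yaxis().set_visible(False)
    ax.xaxis.set_ticks_position("top")
    ticks = np.linspace(start, end, 6)
    ax.set_xticks(ticks)
    ax.set_xticklabels([_format_bp(t) for t in ticks], fontsize=6)
    ax.tick_params(length=2, pad=1)

    if extra_sidecar:
        sidecar.update(extra_sidecar)
    save_kwargs: dict = {}
    if spec.fmt == "png":
        save_kwargs["metadata"] = {"Software": "structatlas"}
    elif spec.fmt == "svg":
        save_kwargs["metadata"] = {"Date": None,
                                   "Description": json.dumps(sidecar)}
    fig.savefig(out_path, format=spec.fmt, **save_kwargs)
    sidecar_path = out_path.with_suffix(".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True) + "\n")
    return sidecar


# ---------------------------------------------------------------------------
# Zoom atlases

def orient_features(features: list[GeneFeature], region_start: int,
                    region_end: int, rc: bool) -> list[GeneFeature]:
    """Map features into region coordinates, flipping them when the region
    is reverse-complemented so a '-' gene reads 5'->3' left to right."""
    length = region_end - region_start
    out = []
    for f in features:
        if f.end <= region_start or f.start >= region_end:
            continue
        s = max(f.start, region_start) - region_start
        e = min(f.end, region_end) - region_start
        exons = [
            (max(xs, region_start) - region_start,
             min(xe, region_end) - region_start)
            for xs, xe in f.exons
            if xe > region_start and xs < region_end
        ]
        if rc:
            s, e = length - e, length - s
            exons = sorted((length - xe, length - xs) for xs, xe in exons)
            strand = "+" if f.strand == "-" else "-"
        else:
            strand = f.strand
        out.append(GeneFeature(gene_id=f.gene_id, strand=strand, start=s,
                               end=e, exons=tuple(exons)))
    return out


def render_zoom(seq: SequenceRecord, gene: GeneFeature, flank: int,
                out_path: str | Path, annotations: list[GeneFeature] | None = None,
                width_px: int = 2500, lanes: list[LaneSpec] | None = None,
                approximate_repeats: bool = False, title: str = "") -> dict:
    """Zoom atlas of one gene plus flanks, oriented 5'->3'.

    '-'-strand genes are reverse-complemented before track computation so
    they read left to right; exons are drawn solid and introns light. The
    lane set swaps GC skew for intrinsic curvature, and the AT-content /
    property window defaults to 0.1% of the plotted length.
    """
    rs = max(0, gene.start - flank)
    re_ = min(seq.length, gene.end + flank)
    if rs != gene.start - flank or re_ != gene.end + flank:
        logger.info("zoom flank truncated at sequence boundary for %s",
                    gene.gene_id)
    rc = gene.strand == "-"
    sub = seq.subsequence(rs, re_, rc=rc)
    feats = orient_features(annotations or [gene], rs, re_, rc)
    tracks = compute_zoom_tracks(sub, approximate_repeats=approximate_repeats)
    spec = AtlasSpec(
        lanes=lanes or zoom_lane_specs(),
        width_px=width_px,
        annotations=feats,
        title=title or f"{gene.gene_id} +/- {flank} bp (5'->3')",
        shade_introns=True,
    )
    extra = {"gene": gene.gene_id, "gene_strand": gene.strand,
             "genomic_region": [rs, re_], "oriented_reverse_complement": rc}
    return render_atlas(sub, spec, tracks, out_path, extra_sidecar=extra)
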