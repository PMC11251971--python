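"""Sequence and annotation I/O plus browser-track export.

All in-memory coordinates are 0-based half-open; the 1-based conventions of
GFF3, GenBank and WIG exist only at the file boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import numpy as np
from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .tracks import Track

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")
# IUPAC one-letter ambiguity codes other than N; mapped to N on ingest.
_AMBIGUOUS = set("RYSWKMBDHV")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """An identified DNA sequence over the alphabet {A, C, G, T, N}."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)

    def subsequence(self, start: int, end: int, rc: bool = False) -> "SequenceRecord":
        sub = self.seq[start:end]
        if rc:
            sub = reverse_complement(sub)
        suffix = f":{start}-{end}" + ("(-)" if rc else "")
        return SequenceRecord(id=self.id + suffix, seq=sub)


def normalize_sequence(raw: str, record_id: str = "?") -> str:
    """Uppercase and collapse non-N IUPAC ambiguity codes to N.

    Raises ``ValueError("not DNA")`` when fewer than 80% of characters are
    A/C/G/T/N after uppercasing (e.g. protein input).
    """
    up = raw.upper().replace("U", "T")
    n_valid = sum(c in _VALID for c in up)
    if up and n_valid / len(up) < 0.8:
        raise ValueError(f"not DNA: record {record_id!r}")
    out = []
    n_mapped = 0
    for c in up:
        if c in _VALID:
            out.append(c)
        else:
            out.append("N")
            n_mapped += 1
    if n_mapped:
        logger.warning(
            "record %s: %d ambiguous/non-nucleotide characters mapped to N",
            record_id, n_mapped,
        )
    return "".join(out)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (one per header, order kept)."""
    records = [
        SequenceRecord(id=rec.id, seq=normalize_sequence(str(rec.seq), rec.id))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


@dataclass(frozen=True)
class GeneFeature:
    """A stranded gene with exon structure, in 0-based half-open coordinates."""

    gene_id: str
    strand: str  # '+' or '-'
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        exons = tuple(self.exons) or ((self.start, self.end),)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if s < self.start or e > self.end:
                raise ValueError(
                    f"exon [{s},{e}) outside span of feature {self.gene_id!r}"
                )
            if prev_end is not None and s < prev_end:
                raise ValueError(f"exons of {self.gene_id!r} overlap or are unsorted")
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        gaps = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                gaps.append((e1, s2))
        return tuple(gaps)


def _read_gff3(path: str | Path) -> list[GeneFeature]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    feats = []
    for gene in db.features_of_type("gene", order_by="start"):
        exons = [
            (c.start - 1, c.end)
            for c in db.children(gene, featuretype=("exon", "CDS"), order_by="start")
        ]
        # prefer exon records over CDS when both are present
        exon_only = [
            (c.start - 1, c.end)
            for c in db.children(gene, featuretype="exon", order_by="start")
        ]
        if exon_only:
            exons = exon_only
        feats.append(
            GeneFeature(
                gene_id=gene.id,
                strand=gene.strand if gene.strand in "+-" else "+",
                start=gene.start - 1,
                end=gene.end,
                exons=tuple(_merge_intervals(exons)),
            )
        )
    return feats


def _read_genbank(path: str | Path) -> list[GeneFeature]:
    feats: list[GeneFeature] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        exons_by_gene: dict[str, list[tuple[int, int]]] = {}
        genes: dict[str, tuple[str, int, int]] = {}
        for f in rec.features:
            name = (
                f.qualifiers.get("gene", f.qualifiers.get("locus_tag", ["?"]))[0]
            )
            strand = "-" if f.location.strand == -1 else "+"
            if f.type == "gene":
                genes[name] = (strand, int(f.location.start), int(f.location.end))
            elif f.type in ("CDS", "exon"):
                parts = [(int(p.start), int(p.end)) for p in f.location.parts]
                exons_by_gene.setdefault(name, []).extend(parts)
        for name, (strand, start, end) in genes.items():
            exons = sorted(set(exons_by_gene.get(name, []) or [(start, end)]))
            feats.append(
                GeneFeature(
                    gene_id=name, strand=strand, start=start, end=end,
                    exons=tuple(_merge_intervals(exons)),
                )
            )
    return feats


def _merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def read_annotations(path: str | Path, format: str = "gff3") -> list[GeneFeature]:
    """Read gene annotations (GFF3 or GenBank) into 0-based GeneFeatures.

    Features without exon/CDS sub-records get a single exon equal to their
    full span, so every feature can be shaded uniformly downstream.
    """
    if format == "gff3":
        return _read_gff3(path)
    if format == "genbank":
        return _read_genbank(path)
    raise ValueError(f"unknown annotation format {format!r}")


# ---------------------------------------------------------------------------
# Track export / import


def _fmt(v: float) -> str:
    return f"{v:.6g}"


def _track_intervals(track: "Track") -> Iterable[tuple[int, int, float]]:
    """Per-value half-open intervals anchored at value centers, step wide."""
    for i, v in enumerate(track.values):
        start = track.start_offset - track.window // 2 + i * track.step
        yield start, start + track.step, float(v)


def write_track(track: "Track", path: str | Path, format: str = "bedgraph",
                chrom: str = "seq") -> None:
    """Export a track as bedGraph, fixedStep WIG, or BED (score = value).

    NaN values become gaps: bedGraph/BED lines are omitted and WIG blocks are
    split. bedGraph runs of identical values are merged into one interval.
    """
    path = Path(path)
    if format == "bedgraph":
        lines = [f"track type=bedGraph name={track.name}"]
        run: list[tuple[int, int, float]] | None = None
        for s, e, v in _track_intervals(track):
            if math.isnan(v):
                if run:
                    lines.append(f"{chrom}\t{run[0]}\t{run[1]}\t{_fmt(run[2])}")
                    run = None
                continue
            if run and run[2] == v and run[1] == s:
                run = [run[0], e, v]
            else:
                if run:
                    lines.append(f"{chrom}\t{run[0]}\t{run[1]}\t{_fmt(run[2])}")
                run = [s, e, v]
        if run:
            lines.append(f"{chrom}\t{run[0]}\t{run[1]}\t{_fmt(run[2])}")
    elif format == "wig":
        lines = [f'track type=wiggle_0 name="{track.name}"']
        block_open = False
        prev_i = None
        for i, v in enumerate(track.values):
            if math.isnan(float(v)):
                block_open = False
                continue
            start0 = track.start_offset - track.window // 2 + i * track.step
            if not block_open or prev_i != i - 1:
                lines.append(
                    f"fixedStep chrom={chrom} start={start0 + 1} "
                    f"step={track.step} span={track.step}"
                )
                block_open = True
            lines.append(_fmt(float(v)))
            prev_i = i
    elif format == "bed":
        lines = []
        for j, (s, e, v) in enumerate(_track_intervals(track)):
            if math.isnan(v):
                continue
            score = int(round(v))
            lines.append(f"{chrom}\t{s}\t{e}\t{track.name}_{j}\t{score}")
    else:
        raise ValueError(f"unknown track format {format!r}")
    path.write_text("\n".join(lines) + "\n")


def read_bedgraph(path: str | Path) -> list[tuple[str, int, int, float]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("track", "#", "browser")):
            continue
        c, s, e, v = line.split("\t")
        out.append((c, int(s), int(e), float(v)))
    return out


def read_wig(path: str | Path) -> list[tuple[str, int, float]]:
    """Return (chrom, 0-based position, value) triples from fixedStep WIG."""
    out = []
    chrom, pos, step = None, 0, 1
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("track", "#")):
            continue
        if line.startswith("fixedStep"):
            kv = dict(tok.split("=") for tok in line.split()[1:])
            chrom = kv["chrom"]
            pos = int(kv["start"]) - 1
            step = int(kv.get("step", 1))
            continue
        out.append((chrom, pos, float(line)))
        pos += step
    return out


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, int]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("track", "#", "browser")):
            continue
        fields = line.split("\t")
        out.append(
            (fields[0], int(fields[1]), int(fields[2]), fields[3], int(fields[4]))
        )
    return out


def expand_bedgraph(intervals: list[tuple[str, int, int, float]],
                    start: int, n: int, step: int) -> np.ndarray:
    """Reconstruct per-value samples from bedGraph intervals (NaN for gaps)."""
    vals = np.full(n, np.nan)
    for _, s, e, v in intervals:
        i0 = (s - start) // step
        i1 = (e - start) // step
        vals[max(i0, 0):min(i1, n)] = v
    return vals
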