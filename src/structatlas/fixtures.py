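"""Deterministic synthetic sequences and annotations for tests and demos.

A FixtureRecipe describes a random background sequence plus typed blocks
(AT/GC-rich stretches, G runs, planted direct/inverted repeat copies,
helically phased A-tracts). Everything is reproducible from
(recipe, seed); recipes round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .seqio import GeneFeature, SequenceRecord, reverse_complement

BASES = np.array(list("ACGT"))

BLOCK_KINDS = ("random", "at_rich", "gc_rich", "g_run",
               "planted_direct_repeat", "planted_inverted_repeat",
               "phased_a_tract")


@dataclass(frozen=True)
class Block:
    kind: str
    start: int
    end: int
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in BLOCK_KINDS:
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad block span [{self.start},{self.end})")


@dataclass(frozen=True)
class FixtureRecipe:
    length: int
    seed: int
    blocks: tuple[Block, ...] = ()
    id: str = "fixture"

    def __post_init__(self):
        object.__setattr__(self, "blocks", tuple(
            b if isinstance(b, Block) else Block(**b) for b in self.blocks))
        planted = [b for b in self.blocks
                   if b.kind.startswith("planted")]
        spans = sorted((b.start, b.end) for b in planted)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("overlapping planted blocks")
        for b in self.blocks:
            if b.end > self.length:
                raise ValueError(f"block [{b.start},{b.end}) outside sequence")

    def to_yaml(self, path: str | Path | None = None) -> str:
        doc = {
            "id": self.id, "length": self.length, "seed": self.seed,
            "blocks": [
                {"kind": b.kind, "start": b.start, "end": b.end,
                 **({"params": b.params} if b.params else {})}
                for b in self.blocks
            ],
        }
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, text_or_path: str | Path) -> "FixtureRecipe":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        doc = yaml.safe_load(text)
        return cls(
            length=doc["length"], seed=doc["seed"], id=doc.get("id", "fixture"),
            blocks=tuple(Block(kind=b["kind"], start=b["start"], end=b["end"],
                               params=b.get("params", {}))
                         for b in doc.get("blocks", ())),
        )


def random_dna(length: int, rng: np.random.Generator,
               p: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
               ) -> str:
    return "".join(rng.choice(BASES, size=length, p=list(p)))


def make_sequence(recipe: FixtureRecipe) -> SequenceRecord:
    """Realise a recipe as a SequenceRecord (deterministic for its seed)."""
    rng = np.random.default_rng(recipe.seed)
    arr = np.array(list(random_dna(recipe.length, rng)))
    # non-planted blocks first, then planted copies (so a copy of a styled
    # source span reproduces the styled content exactly)
    for b in recipe.blocks:
        n = b.end - b.start
        if b.kind == "at_rich":
            p_at = b.params.get("p_at", 1.0)
            probs = (p_at / 2, (1 - p_at) / 2, (1 - p_at) / 2, p_at / 2)
            arr[b.start:b.end] = list(random_dna(n, rng, probs))
        elif b.kind == "gc_rich":
            p_gc = b.params.get("p_gc", 1.0)
            probs = ((1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2)
            arr[b.start:b.end] = list(random_dna(n, rng, probs))
        elif b.kind == "g_run":
            arr[b.start:b.end] = "G"
        elif b.kind == "phased_a_tract":
            period = b.params.get("period", 10.5)
            tract_len = b.params.get("tract_len", 6)
            pos = 0.0
            while int(pos) + tract_len <= n:
                i = b.start + int(pos)
                arr[i:i + tract_len] = "A"
                pos += period
        elif b.kind == "random":
            arr[b.start:b.end] = list(random_dna(n, rng))
    for b in recipe.blocks:
        if b.kind in ("planted_direct_repeat", "planted_inverted_repeat"):
            src = b.params["source_start"]
            n = b.end - b.start
            copy = "".join(arr[src:src + n])
            if b.kind == "planted_inverted_repeat":
                copy = reverse_complement(copy)
            arr[b.start:b.end] = list(copy)
    return SequenceRecord(id=recipe.id, seq="".join(arr))


def write_fasta(record: SequenceRecord, path: str | Path, width: int = 70) -> None:
    lines = [f">{record.id}"]
    for i in range(0, record.length, width):
        lines.append(record.seq[i:i + width])
    Path(path).write_text("\n".join(lines) + "\n")


def make_annotation(genes: list[dict], path: str | Path | None = None,
                    seqid: str = "fixture") -> list[GeneFeature]:
    """Build toy GeneFeatures and (optionally) the matching GFF3 file.

    Each gene dict: ``gene_id``, ``strand``, ``start``, ``end`` (0-based
    half-open) and optional ``exons`` (list of [start, end)).
    """
    feats = [
        GeneFeature(gene_id=g["gene_id"], strand=g["strand"], start=g["start"],
                    end=g["end"], exons=tuple(tuple(x) for x in g.get("exons", ())))
        for g in genes
    ]
    if path is not None:
        lines = ["##gff-version 3"]
        for f in feats:
            lines.append("\t".join([
                seqid, "structatlas", "gene", str(f.start + 1), str(f.end),
                ".", f.strand, ".", f"ID={f.gene_id}",
            ]))
            for i, (s, e) in enumerate(f.exons):
                lines.append("\t".join([
                    seqid, "structatlas", "exon", str(s + 1), str(e),
                    ".", f.strand, ".",
                    f"ID={f.gene_id}.e{i};Parent={f.gene_id}",
                ]))
        Path(path).write_text("\n".join(lines) + "\n")
    return feats


# ---------------------------------------------------------------------------
# Ready-made recipes used by the CLI demo and the acceptance script

def demo_haplotype_recipe(length: int = 50_000, seed: int = 7) -> FixtureRecipe:
    """A miniature haplotype-like fixture: AT-rich and GC-rich stretches,
    one distant direct repeat pair, one inverted pair, and a phased A-tract
    block (a curvature hotspot)."""
    L = length
    return FixtureRecipe(
        length=L, seed=seed, id="synthetic_haplotype",
        blocks=(
            Block("at_rich", int(L * 0.10), int(L * 0.16), {"p_at": 0.9}),
            Block("gc_rich", int(L * 0.55), int(L * 0.61), {"p_gc": 0.9}),
            Block("phased_a_tract", int(L * 0.30), int(L * 0.32)),
            Block("planted_direct_repeat", int(L * 0.75), int(L * 0.75) + 400,
                  {"source_start": int(L * 0.40)}),
            Block("planted_inverted_repeat", int(L * 0.88), int(L * 0.88) + 400,
                  {"source_start": int(L * 0.22)}),
        ),
    )


def demo_genes(length: int = 50_000) -> list[dict]:
    L = length
    g1s = int(L * 0.40)
    g2s = int(L * 0.62)
    return [
        {"gene_id": "geneA", "strand": "+", "start": g1s, "end": g1s + 3000,
         "exons": [[g1s, g1s + 600], [g1s + 1400, g1s + 2100],
                   [g1s + 2600, g1s + 3000]]},
        {"gene_id": "geneB", "strand": "-", "start": g2s, "end": g2s + 2400,
         "exons": [[g2s, g2s + 500], [g2s + 1500, g2s + 2400]]},
    ]
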