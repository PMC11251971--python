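"""Published k-mer structural parameter sets and per-position profile lookup.

Three scales ship with the package as plain-text data files so their
completeness and strand symmetry can be asserted by tests without touching
code:

* ``stacking_energy`` — dinucleotide base-stacking energies in kcal/mol
  (Ornstein et al. 1978). Values are negative; small magnitudes mark DNA
  that melts easily.
* ``position_preference`` — trinucleotide nucleosome-positioning
  preferences (Satchwell et al. 1986). Low values suggest DNA that resists
  wrapping around nucleosomes, i.e. potentially open chromatin.
* ``curvature`` — a dinucleotide wedge model of intrinsic curvature
  (Bolshoy et al. 1991 wedge angles with Kabsch/Sander/Trifonov helical
  twist). The model is pluggable: any CurvatureModel instance may replace
  the packaged default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .seqio import SequenceRecord, reverse_complement

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]


@dataclass(frozen=True)
class PropertyScale:
    """A complete k-mer -> value lookup for one structural property."""

    name: str
    k: int
    values: dict[str, float]
    units: str
    citation: str
    strand_symmetric: bool

    def is_complete(self) -> bool:
        return set(self.values) == set(all_kmers(self.k))

    def symmetry_violations(self) -> list[str]:
        return [
            kmer for kmer in self.values
            if self.values[kmer] != self.values[reverse_complement(kmer)]
        ]

    def as_array(self) -> np.ndarray:
        """Values indexed by base-4 k-mer code (A=0, C=1, G=2, T=3)."""
        arr = np.empty(4 ** self.k)
        for kmer, v in self.values.items():
            code = 0
            for c in kmer:
                code = code * 4 + _BASE_INDEX[c]
            arr[code] = v
        return arr


@dataclass(frozen=True)
class CurvatureModel:
    """Dinucleotide wedge-angle model of intrinsic DNA curvature.

    Each step deflects the helix axis by ``wedge`` degrees in direction
    ``direction`` (degrees, in the plane normal to the axis, rotating with
    the helix by ``twist`` degrees per step). Curvature over a window is the
    magnitude of the vector sum of the phased wedges, in degrees per step:
    wedges repeating in helical phase (e.g. A-tracts every ~10.5 bp) add
    coherently, random sequence cancels.
    """

    name: str
    wedge: dict[str, float]     # degrees
    direction: dict[str, float]  # degrees
    twist: dict[str, float]     # degrees per step
    window_len: int             # bp window of the phased sum
    citation: str

    def is_complete(self) -> bool:
        kmers = set(all_kmers(2))
        return set(self.wedge) == kmers and set(self.direction) == kmers \
            and set(self.twist) == kmers

    def finite(self) -> bool:
        vals = (list(self.wedge.values()) + list(self.direction.values())
                + list(self.twist.values()))
        return bool(np.all(np.isfinite(vals)))


def straight_model(window_len: int = 21) -> CurvatureModel:
    """All-zero-wedge control model: curvature is identically zero."""
    kmers = all_kmers(2)
    return CurvatureModel(
        name="straight_control",
        wedge={k: 0.0 for k in kmers},
        direction={k: 0.0 for k in kmers},
        twist={k: 34.3 for k in kmers},
        window_len=window_len,
        citation="synthetic zero-deflection control",
    )


def _parse_scale_text(text: str) -> tuple[dict[str, str], list[list[str]]]:
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    for line in text.splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            key, _, val = line[1:].partition("\t")
            meta[key] = val
        else:
            rows.append(line.split("\t"))
    return meta, rows


BUILTIN_SCALES = ("stacking_energy", "position_preference", "curvature")
_FILES = {
    "stacking_energy": "stacking_energy.tsv",
    "position_preference": "position_preference.tsv",
    "curvature": "curvature_wedge.tsv",
}


def load_builtin_scale(name: str) -> PropertyScale | CurvatureModel:
    """Load a packaged scale by name; unknown names list what is available."""
    if name not in _FILES:
        raise ValueError(
            f"unknown scale {name!r}; available: {', '.join(BUILTIN_SCALES)}"
        )
    text = (resources.files("structatlas") / "data" / _FILES[name]).read_text()
    meta, rows = _parse_scale_text(text)
    if name == "curvature":
        wedge, direction, twist = {}, {}, {}
        for kmer, w, d, t in rows:
            wedge[kmer] = float(w)
            direction[kmer] = float(d)
            twist[kmer] = float(t)
        return CurvatureModel(
            name=meta["name"], wedge=wedge, direction=direction, twist=twist,
            window_len=int(meta["window_len"]), citation=meta["citation"],
        )
    return PropertyScale(
        name=meta["name"],
        k=int(meta["k"]),
        values={kmer: float(v) for kmer, v in rows},
        units=meta["units"],
        citation=meta["citation"],
        strand_symmetric=meta["strand_symmetric"].lower() == "true",
    )


def encode(seq: str | SequenceRecord) -> np.ndarray:
    """Encode A/C/G/T as 0..3 and N as 4, as an int8 array."""
    s = seq.seq if isinstance(seq, SequenceRecord) else seq
    raw = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    table = np.full(128, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
    return table[raw]


def lookup_profile(seq: SequenceRecord | str, scale: PropertyScale) -> np.ndarray:
    """Per-position profile: position i holds values[seq[i:i+k]].

    Output length is ``len(seq) - k + 1``; any k-mer containing N yields NaN.
    """
    codes = encode(seq)
    k = scale.k
    if k > len(codes):
        raise ValueError("scale k exceeds sequence length")
    valid = codes < 4
    safe = np.where(valid, codes, 0).astype(np.int64)
    idx = np.zeros(len(codes) - k + 1, dtype=np.int64)
    ok = np.ones(len(codes) - k + 1, dtype=bool)
    for j in range(k):
        idx = idx * 4 + safe[j:j + len(idx)]
        ok &= valid[j:j + len(idx)]
    prof = scale.as_array()[idx]
    prof[~ok] = np.nan
    return prof
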