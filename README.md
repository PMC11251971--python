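# structatlas

Structural properties of DNA — how easily it melts, how willingly it wraps
around nucleosomes, how intrinsically curved it is, where it repeats
itself — are encoded in the base sequence but invisible when you read it.
`structatlas` computes these properties from a raw DNA sequence (for
example a complete MHC haplotype) as windowed tracks, and renders them as
**structural atlases**: fixed-width, multi-lane linear figures in which
each color lane shows one property along the sequence at a stated
bp-per-pixel resolution. It is aimed at anyone inspecting large (kb-Mb)
genomic regions for structural variation: regions likely to form open
chromatin, melt easily, bend around proteins, or harbour large direct or
inverted repeats.

## What is computed

Given a sequence *S* of length *L*:

* **Stacking energy** — per-dinucleotide stacking energies ΔG(s<sub>i</sub>s<sub>i+1</sub>)
  (kcal/mol, Ornstein et al. 1978), averaged over a sliding window. Values
  near zero mark DNA that melts easily.
* **Position preference** — per-trinucleotide nucleosome positioning
  preferences (Satchwell et al. 1986), window-averaged. Low values suggest
  DNA that resists nucleosome wrapping — potentially open chromatin.
* **Curvature** — intrinsic curvature from a dinucleotide wedge model
  (Bolshoy et al. 1991): each step contributes a wedge vector phased by the
  cumulative helical twist; the magnitude of the vector sum over ~two
  helical turns (deg/step) is high where bends repeat in phase (A-tracts
  every ~10.5 bp).
* **GC skew** — (G−C)/(G+C) per window (default 10 kb), in [−1, 1].
* **AT content** — (A+T)/window, window defaulting to 0.1% of the plotted
  length.
* **Direct / inverted repeats** — for each 100-bp query window, the best
  ungapped identity against every other window of the sequence (direct) or
  of its reverse complement (inverted), excluding self-overlap, binned
  0–9: bin 9 = more than 90% identity, bin 0 = less than 10%. Values are
  plotted from 50 bp to within 50 bp of the sequence end. A seeded k-mer
  search with full verification returns *exactly* the same identities as
  the exhaustive scan (the seed guarantee plus an exhaustive fallback).

An atlas stacks these lanes over a strand-separated gene lane and a scale
bar; the resolution is `region_length / width_px` bp/pixel (a 4.93-Mbp
locus at the default 2,500 px width is 1972 bp/pixel). Gene **zoom**
atlases swap the GC-skew lane for the curvature lane, shade introns light,
and reverse-complement minus-strand genes so they always read 5′→3′.

## Worked example

```bash
python - <<'EOF'
from structatlas.fixtures import (demo_haplotype_recipe, demo_genes,
                                  make_sequence, make_annotation, write_fasta)
seq = make_sequence(demo_haplotype_recipe(50_000, seed=7))
write_fasta(seq, "hap.fasta")
make_annotation(demo_genes(50_000), "genes.gff3", seqid=seq.id)
EOF
structatlas atlas -i hap.fasta -a genes.gff3 -o out/ --width-px 2500
structatlas zoom  -i hap.fasta -a genes.gff3 --gene geneB --flank 3000 -o out/
```

The atlas command logs

```
INFO structatlas: atlas synthetic_haplotype: resolution 20 bp/px
```

and writes `out/atlas_synthetic_haplotype.png` (a 2,500-px-wide atlas: six
structural lanes + gene lane + scale bar), a sidecar JSON recording
per-lane mean/SD/window/step and the 20.0 bp/pixel resolution
(50,000 bp / 2,500 px), four bedGraph tracks and two BED repeat tracks.
In the image, the planted AT-rich block shows red in the stacking-energy
and AT-content lanes (easily melting, AT-rich DNA), the planted 400-bp
direct-repeat pair appears as bin-9 bars in the direct-repeat lane at both
copies, and the zoom of `geneB` (a minus-strand gene) renders it 5′→3′
with solid exons and light introns at `8400/2500 = 3.36` bp/pixel.

Single tracks export to genome-browser formats:

```bash
structatlas tracks -i hap.fasta --track gc_skew --window 10000 \
    --format bedgraph -o skew.bedgraph
```

and `structatlas compare -i a.fasta -i b.fasta -o out/` stacks several
atlases at matched pixel width, reporting each input's own bp/pixel
resolution.

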