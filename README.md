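# ssduplex

Duplex consensus sequencing error correction — UMI-free, fragment-coordinate
based — together with a mechanistic simulator of the **single-strand (SS)
end-repair artifacts** that duplex consensus *cannot* correct, and of the
single-strand-specific nuclease (SSN) treatment that removes them.

## The problem

Duplex consensus sequencing reaches error rates below 10⁻⁷ per base by
requiring that a variant be seen independently on **both strands** of one
original DNA molecule: read pairs sharing exact fragment coordinates are
grouped into same-position groups (SP-Gs), split into their two orientation
families (F1R2/F2R1 — the coordinate proxy for the two strands), and a
double-strand consensus sequence (dsDCS) is emitted only where the two
strand consensuses agree.

This logic has a blind spot. Acoustic shearing leaves fragment ends with
single-strand overhangs, plus internal nicks and gaps. Guanine in these SS
regions is vulnerable to oxidation (8-oxoG, which pairs with A, and
2-aminoimidazolone, which pairs with G) and cytosine to deamination. During
library preparation, **end repair fills in 5′ overhangs and gaps using the
damaged strand as template**, converting a single-strand lesion into a
*concordant* double-strand substitution — both strands now agree on the
wrong base, and duplex consensus reports it as a confident mutation:

* 8-oxoG → G>T, Iz → G>C, deaminated C → C>T, always read on the strand
  that carried the lesion.

Because the damaged strand at a fragment end is always the one whose 5′
terminus the inward-sequencing read starts from, these artifacts are
strand-asymmetric in the **fragment (read-orientation) frame**: G>T ≫ C>A
and G>C ≫ C>G. That asymmetry — the 12-type strand-resolved spectrum — is
the artifact fingerprint, and the package reproduces the two known
counter-measures:

1. **read clipping** (mask k bases at each fragment end): reduces but never
   eliminates the artifacts, because gaps and nicks sit in the fragment
   interior;
2. **SSN digestion before end repair** (S1-, mung-bean- and RecJf-like
   models): excises the SS regions themselves. The S1 model (overhangs,
   gaps, nicks) removes essentially all artifacts; RecJf (5′ overhangs
   only) leaves interior lesions behind — exactly the ordering used to
   argue that interior SS structure, not just overhangs, carries damage.

Everything runs at desk scale on simulated molecules with full truth
tables; no real sequencing data is needed. Frequencies are reported per
10⁶ counted bases as 12-type (strand-resolved) and 6-type (complement
pooled: e.g. G:C>T:A = G>T + C>A over the summed G and C denominators)
spectra, with Student's *t* or Dunnett's many-to-one test, log₂ fold
change and −log₁₀ *p* per mutation type.

## Worked example

`examples/03_mutation_spectrum.py` simulates 5 000 fragments (350 bp peak,
geometric mean-8 bp overhangs, 2 %/G oxidation in SS regions), calls the
duplex consensus and prints the fragment-frame spectrum under clipping:

```
clip  freq(G>T)  freq(C>A)  ratio   (per 1e6 bp, fragment frame)
   0     534.37      11.54   46.3
  10     154.72      12.84   12.1
  20      82.21       9.63    8.5
In reference frame the same events split symmetrically:
      freq(G>T) 292.08  freq(C>A) 252.01
```

Reading this: in the fragment frame every end-repair artifact counts as a
G-strand event, so G>T dwarfs its complement C>A (ratio 46 at clip 0);
clipping 10 then 20 bases removes the overhang-borne artifacts but a
residual from interior gaps/nicks survives (ratio still ≫ 1). In the
reference frame the same lesions land on either genome strand equally, so
the asymmetry — and the fingerprint — disappears. The other example
scripts (`examples/01…05`) cover simulation output, duplex suppression of
discordant noise (~2 500× here), the nuclease head-to-head and
coverage/misassignment QC.

The same operations are available from the shell:

```bash
ssduplex simulate --outdir sim --seed 1
ssduplex consensus --in sim/sim.truth.sam --out sim/dcs.sam
ssduplex spectrum --dcs sim/dcs.sam --ref sim/sim.genome.fa --clip 0 --out sim/spec.tsv
ssduplex covqc --dcs sim/dcs.sam --ref sim/sim.genome.fa --out-prefix sim/qc
ssduplex experiment --config run.yaml --outdir grid --seed 1
```

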