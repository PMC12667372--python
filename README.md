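# obliphase

Data-oblivious reference-based haplotype phasing: a Li–Stephens HMM over a
genotype graph, with conditioned reference panels selected through a
compressed-PBWT prefix-tree structure, all secret-dependent arithmetic in
dynamically scaled fixed point.

## The problem

Phasing partitions an individual's diploid genotypes g ∈ {0,1,2}ⁿ into the
two parental haplotype sequences, using a large panel of known phased
haplotypes as reference.  When the computation runs on untrusted
infrastructure (e.g. inside a secure enclave on a service provider's
machine), the *memory-access patterns and control flow* of an ordinary
phasing algorithm leak the private genotypes through side channels.
`obliphase` is an algorithm-level re-design for that setting, aimed at
people studying oblivious genomic algorithms: every secret-dependent step
has an access pattern that depends only on public shapes, enforced by a
`Secret` type discipline and verified by an access-trace harness, and all
secret-dependent arithmetic avoids floating point.

## The method

- **Genotype graph** — heterozygous sites are segmented (3 hets/segment by
  default); the 2^h phase options per segment make every consistent
  haplotype pair a path through the segment chain.
- **Diploid Li–Stephens HMM** — state (k₁, k₂, option): each target
  haplotype is a mosaic of K conditioned reference haplotypes with switch
  probability ρᵢ = 1 − exp(−0.04·Ne·dᵢ/K) per interval and allele-copy
  error ε = 10⁻⁴.  MCMC alternates burn-in sampling from the
  segment-transition posteriors, pruning of high-confidence transitions,
  and final Viterbi decoding.
- **Compressed PBWT selection** — the panel is tiled into blocks keeping
  only unique haplotype rows (M3VCF-style); per-block PBWT prefix trees
  with divergence values are built once from the public panel.  The current
  phase estimate is inserted obliviously, the S nearest neighbours by
  longest suffix match are found at one random position per segment (with
  global match lengths carried across block boundaries), and their union —
  held as a bitmap, padded to a fixed public capacity — forms the
  conditioned panel.
- **Dynamic fixed point** — integer mantissas with one power-of-two
  exponent per matrix row, renormalised so each row's maximum lies in
  [0.5, 1).  Long products of small probabilities that annihilate a static
  fixed-point representation keep their full relative structure.
- **Oblivious primitives** — linear-scan ORAM, bitonic sorting/filtering,
  branch-free multiplexers and constant-iteration long division underneath
  everything above.

See `docs/methods.md` for the full model, parameter defaults and design
rationale.

## Worked example

```python
import numpy as np
from obliphase import (SimConfig, PhaseConfig, simulate_panel, make_target,
                       mcmc_run, switch_error_rate)
from obliphase.panel import compress_panel

cfg = SimConfig(n_hap=200, n_sites=500, target_recombs=3,
                genotype_error=0.002, seed=0)
rng = np.random.default_rng(0)
panel = simulate_panel(cfg, rng)          # founder-mosaic reference panel
truth = make_target(panel, cfg, rng)      # diploid target with known phase

cp = compress_panel(panel)
uniq = sum(b.n_unique for b in cp.blocks)
print(f"panel: {panel.n_hap} haplotypes x {panel.n_sites} sites")
print(f"compressed: {len(cp.blocks)} blocks, {uniq} unique rows "
      f"(ratio {uniq / (panel.n_hap * len(cp.blocks)):.3f})")
print(f"target: {(truth.genotypes == 1).sum()} heterozygous sites, "
      f"{len(truth.error_sites)} genotype errors")

est = mcmc_run(truth.genotypes, panel, PhaseConfig(),
               np.random.default_rng(10_000))
print(f"switch error rate: {100 * switch_error_rate(est, truth):.2f}%")
```

prints

```
panel: 200 haplotypes x 500 sites
compressed: 16 blocks, 756 unique rows (ratio 0.236)
target: 187 heterozygous sites, 1 genotype errors
switch error rate: 0.00%
```

The compression ratio (unique rows per block over panel haplotypes) is what
makes oblivious neighbour search affordable: PBWT queries touch 0.236× the
rows a full scan would.  The switch error rate is the fraction of
consecutive heterozygous pairs phased with the wrong relative orientation —
here the target's mosaic structure (3 recombinations per haplotype, one
dosage error) is recovered exactly.

## Command line

```sh
obliphase simulate --out-prefix sim --seed 0        # panel/target/truth VCFs
obliphase phase --panel sim.panel.vcf --target sim.target.vcf \
    --out phased.vcf --seed 1                       # phase a sample
obliphase compress --panel sim.panel.vcf --out sim.cpanel.txt
obliphase bench --out bench.tsv --n-seeds 5         # dynamic vs static SER
obliphase audit-traces --seed 0                     # trace-equality audit
```

Fixed seed and inputs give byte-identical output VCFs.  `--audit-traces` on
`phase` runs each iteration twice with resampled secrets and asserts the
access traces are identical.

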