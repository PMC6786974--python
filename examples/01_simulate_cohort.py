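"""Simulate a small imaging-genetics cohort and write it to disk.

The generator produces imputed genotype dosages with local LD and a genetic
map, acquisition covariates (age, sex, scan date, head motion, head size,
position), and phenotypes drawn from the matrix-normal model
Y = G alpha + U + eps with a known truth set, so every downstream example can
check its answers against the generating parameters.

Run:  python examples/01_simulate_cohort.py
"""

import tempfile
from pathlib import Path

import numpy as np

import mtgwas as m

# --- simulate each piece explicitly ---------------------------------------
G = m.simulate_genotypes(n_samples=400, n_variants=800, seed=7,
                         n_chromosomes=2)
print(f"genotypes: {G.n_samples} samples x {G.n_variants} variants, "
      f"MAF range [{G.variants.maf.min():.3f}, {G.variants.maf.max():.3f}]")

cov = m.simulate_covariates(400, seed=8)
print(f"covariates: ages {cov.age.min():.0f}-{cov.age.max():.0f}, "
      f"{int(cov.sex.sum())} of {len(cov.sex)} coded 1, "
      f"scan dates span {np.ptp(cov.scan_date):.0f} days")

# a truth set fixes B, E and a sparse list of causal (variant, trait) effects
truth = m.random_truth(n_phenotypes=6, n_variants=G.n_variants, seed=9)
print("planted causal effects (variant index, trait index, beta):")
for v, p, eff in truth.causal_effects:
    print(f"  variant {v:4d} -> trait {p}  beta = {eff:+.3f}")

K = m.make_block_kinship(400, family_size=5, relatedness=0.4)
Y = m.simulate_phenotypes(G, K, truth,
                          groups=["area"] * 3 + ["conn"] * 3,
                          group_missingness={"conn": 0.1})
miss = np.isnan(Y.values).mean(axis=0)
print(f"phenotypes: {Y.values.shape}, per-trait missingness "
      f"{np.round(miss, 3)}")

# --- or write a complete bundle in one call --------------------------------
with tempfile.TemporaryDirectory() as tmp:
    paths = m.make_fixture("tiny", seed=7, out_dir=tmp)
    print("\nfixture bundle:")
    for name, path in paths.items():
        print(f"  {name:12s} {Path(path).name}")
    G2 = m.read_vcf_dosages(paths["vcf"], map_path=paths["map"])
    print(f"round-trip through VCF: {G2.n_samples} samples, "
          f"{G2.n_variants} variants, dosages match:",
          np.allclose(G2.dosages,
                      m.read_vcf_dosages(paths["vcf"]).dosages))
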