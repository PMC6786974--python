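"""Mass univariate GWAS, multiple-testing thresholds, clumping, replication
and a PheWAS profile, end to end on a synthetic cohort with planted signals.

Run:  python examples/03_mass_gwas_and_loci.py
"""

import numpy as np

import mtgwas as m

# --- cohort with three planted causal variants ------------------------------
n = 1200
G = m.simulate_genotypes(n, 1500, seed=50, n_chromosomes=2)
truth = m.random_truth(n_phenotypes=8, n_variants=1500, seed=51,
                       effect_size=0.35)
Y = m.simulate_phenotypes(G, np.eye(n), truth,
                          groups=["vol"] * 4 + ["conn"] * 4)
print("planted:", [(v, p) for v, p, _ in truth.causal_effects])

# --- variant QC --------------------------------------------------------------
G_qc, report = m.variant_qc(G, maf_min=0.001, info_min=0.3, hwe_p_min=1e-7)
print(f"QC: kept {report.n_pass}/{report.n_input} "
      f"(MAF fails {report.n_fail_maf}, INFO fails {report.n_fail_info}, "
      f"HWE fails {report.n_fail_hwe})")

# --- mass univariate scan ----------------------------------------------------
res = m.run_mass_gwas(G_qc, Y)
print(f"associations computed: {len(res)} "
      f"({G_qc.n_variants} variants x {len(Y.names)} phenotypes)")

# --- thresholds for this study size -----------------------------------------
t = m.thresholds(n_phenotypes=len(Y.names), n_groups=2)
print(f"thresholds: genome-wide {t.genomewide}, study-wide {t.studywide}, "
      f"PheWAS {t.phewas}")

# --- clump to lead variants and cluster into loci ---------------------------
hits = res[res.neglog10_p > t.genomewide]
leads = m.prune_leads(res, threshold=t.genomewide, window_cm=0.25)
clusters = m.cluster_leads(leads, window_cm=0.25)
print(f"\n{len(hits)} significant associations -> {len(leads)} leads -> "
      f"{len(clusters)} clusters")
for c in clusters:
    print(f"  chr{c.chrom} [{c.cm_low:.3f}, {c.cm_high:.3f}] cM "
          f"lead {c.lead_variant} "
          f"(-log10 P = {c.lead_neglog10_p:.1f}) phenotypes {c.phenotypes}")

# --- replication in an independent cohort ------------------------------------
G2 = m.simulate_genotypes(n, 1500, seed=52, n_chromosomes=2)
Y2 = m.simulate_phenotypes(G2, np.eye(n), truth)
res2 = m.run_mass_gwas(G2, Y2).set_index(["variant", "phenotype"])
pairs = list(zip(leads["variant"], leads["phenotype"]))
rep_nlp = np.array([res2.loc[pr, "neglog10_p"] for pr in pairs])
rep_beta = np.array([res2.loc[pr, "beta"] for pr in pairs])
rep = m.assess_replication(10.0 ** (-rep_nlp),
                           discovery_beta=leads["beta"].to_numpy(),
                           replication_beta=rep_beta)
print(f"\nreplication: {rep.n_nominal}/{rep.n_leads} nominal, "
      f"{rep.n_fdr} after FDR, {rep.sign_concordant} sign-concordant "
      f"(expected by chance: {rep.expected_null})")

# --- PheWAS: one lead variant against every phenotype ------------------------
top = leads.iloc[0]["variant"]
prof = m.phewas_profile(top, res, threshold=t.phewas)
flagged = prof.loc[prof.above_threshold, "phenotype"].tolist()
print(f"\nPheWAS of {top}: associated with {flagged} "
      f"at -log10 P > {t.phewas}")
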