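"""Lead variants, cross-phenotype locus clusters, multiplicity thresholds,
replication assessment and PheWAS profiles.

Leads are found per phenotype by greedy pruning: take the most strongly
associated variant above the significance threshold, remove everything
within a genetic-map window (0.25 cM by default) and repeat.  Leads from all
phenotypes are then chained into clusters by single linkage within the same
window.  Multiplicity thresholds follow the standard -log10 bookkeeping: a
genome-wide 7.5, a study-wide 7.5 + log10(#phenotypes) (Bonferroni factor
rounded to one decimal), a multi-trait-scan threshold 7.5 + log10(#groups),
and a PheWAS threshold -log10(0.05 / #phenotypes) truncated to two decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = [
    "ThresholdSet", "LocusCluster", "thresholds", "prune_leads",
    "cluster_leads", "assess_replication", "ReplicationReport",
    "phewas_profile", "benjamini_hochberg",
]

GENOMEWIDE_NEGLOG10P = 7.5
DEFAULT_WINDOW_CM = 0.25


# ---------------------------------------------------------------------------
# Thresholds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdSet:
    genomewide: float
    studywide: float
    multitrait_corrected: float
    phewas: float
    bonferroni_factor: float


def thresholds(n_phenotypes: int, n_groups: int = 1,
               genomewide: float = GENOMEWIDE_NEGLOG10P) -> ThresholdSet:
    """Multiplicity thresholds on the -log10 P scale.

    The study-wide threshold adds the Bonferroni factor log10(n_phenotypes)
    rounded to one decimal; the multi-trait threshold adds log10(n_groups)
    (reported to two decimals); the PheWAS threshold is -log10(0.05 /
    n_phenotypes) truncated to two decimals.
    """
    if n_phenotypes < 1 or n_groups < 1:
        raise ParameterError("counts must be >= 1")
    bonf = round(math.log10(n_phenotypes), 1)
    studywide = genomewide + bonf
    multitrait = round(genomewide + math.log10(n_groups), 2)
    phewas = math.floor(-math.log10(0.05 / n_phenotypes) * 100) / 100
    return ThresholdSet(genomewide=genomewide, studywide=studywide,
                        multitrait_corrected=multitrait, phewas=phewas,
                        bonferroni_factor=bonf)


# ---------------------------------------------------------------------------
# Greedy lead pruning
# ---------------------------------------------------------------------------

def prune_leads(assocs: pd.DataFrame, threshold: float = GENOMEWIDE_NEGLOG10P,
                window_cm: float = DEFAULT_WINDOW_CM,
                maf_min: float = 0.001) -> pd.DataFrame:
    """Greedy lead-variant pruning for one phenotype's association records.

    Records need columns ``variant, chrom, pos, cm, maf, neglog10_p``.  The
    MAF filter (strict >) is applied first; then, repeatedly, the strongest
    remaining variant above ``threshold`` becomes a lead and every variant
    within ``window_cm`` of it on the same chromosome is removed.  Ties break
    to the lowest (chrom, pos).  Leads are returned in discovery order.
    """
    df = assocs.copy()
    if "cm" not in df.columns:
        df["cm"] = df["pos"] / 1e6  # 1 cM per Mb fallback
    df = df[df["maf"] > maf_min]
    df = df[df["neglog10_p"] > threshold]
    missing_cm = df["cm"].isna()
    if missing_cm.any():
        bad = df.loc[missing_cm, "variant"].iloc[0]
        raise ParameterError(f"variant {bad} has no genetic-map (cM) position")
    df = df.sort_values(["neglog10_p", "chrom", "pos"],
                        ascending=[False, True, True], kind="stable")
    leads = []
    alive = df.reset_index(drop=True)
    while len(alive):
        lead = alive.iloc[0]
        leads.append(lead)
        same = (alive["chrom"] == lead["chrom"]) & \
               ((alive["cm"] - lead["cm"]).abs() <= window_cm)
        alive = alive[~same]
    if not leads:
        return df.iloc[0:0]
    return pd.DataFrame(leads).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Cross-phenotype clustering
# ---------------------------------------------------------------------------

@dataclass
class LocusCluster:
    cluster_id: int
    chrom: str
    cm_low: float
    cm_high: float
    members: pd.DataFrame                 # lead rows, incl. phenotype column
    lead_variant: str = ""
    lead_neglog10_p: float = float("nan")
    phenotypes: list[str] = field(default_factory=list)
    maf_tier: str | None = None

    def __post_init__(self) -> None:
        if len(self.members):
            m = self.members.sort_values(["neglog10_p", "chrom", "pos"],
                                         ascending=[False, True, True], kind="stable")
            self.lead_variant = str(m.iloc[0]["variant"])
            self.lead_neglog10_p = float(m.iloc[0]["neglog10_p"])
            if "phenotype" in self.members.columns:
                self.phenotypes = sorted(set(map(str, self.members["phenotype"])))

    @property
    def cm_span(self) -> float:
        return self.cm_high - self.cm_low


def cluster_leads(leads: pd.DataFrame, window_cm: float = DEFAULT_WINDOW_CM,
                  curation: list[dict] | None = None) -> list[LocusCluster]:
    """Single-linkage chaining of lead variants (possibly from many
    phenotypes) within ``window_cm`` on the same chromosome.

    ``curation`` is an optional list of manual directives applied after the
    automatic pass: ``{"action": "merge", "clusters": [i, j, ...]}`` or
    ``{"action": "split", "cluster": i, "at_cm": x}``.
    """
    if leads.empty:
        return []
    clusters: list[pd.DataFrame] = []
    for chrom, grp in leads.groupby("chrom", sort=True):
        grp = grp.sort_values("cm", kind="stable")
        start = 0
        cm = grp["cm"].to_numpy(float)
        for i in range(1, len(grp)):
            if cm[i] - cm[i - 1] > window_cm:
                clusters.append(grp.iloc[start:i])
                start = i
        clusters.append(grp.iloc[start:])

    def build(members: pd.DataFrame, cid: int) -> LocusCluster:
        return LocusCluster(cluster_id=cid, chrom=str(members.iloc[0]["chrom"]),
                            cm_low=float(members["cm"].min()),
                            cm_high=float(members["cm"].max()),
                            members=members.reset_index(drop=True))

    out = [build(m, i) for i, m in enumerate(clusters)]

    for directive in curation or []:
        action = directive.get("action")
        if action == "merge":
            ids = set(directive["clusters"])
            merged = pd.concat([c.members for c in out if c.cluster_id in ids],
                               ignore_index=True)
            out = [c for c in out if c.cluster_id not in ids]
            out.append(build(merged, min(ids)))
        elif action == "split":
            cid, at = directive["cluster"], float(directive["at_cm"])
            target = next(c for c in out if c.cluster_id == cid)
            out = [c for c in out if c.cluster_id != cid]
            left = target.members[target.members["cm"] <= at]
            right = target.members[target.members["cm"] > at]
            next_id = max((c.cluster_id for c in out), default=-1) + 1
            if len(left):
                out.append(build(left, cid))
            if len(right):
                out.append(build(right, next_id))
        else:
            raise ParameterError(f"unknown curation action {action!r}")
    return sorted(out, key=lambda c: (c.chrom, c.cm_low))


# ---------------------------------------------------------------------------
# Replication
# ---------------------------------------------------------------------------

def benjamini_hochberg(pvalues: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Boolean mask of discoveries under BH FDR control at level q."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    crit = q * np.arange(1, n + 1) / n
    passing = ranked <= crit
    k = np.max(np.nonzero(passing)[0]) + 1 if passing.any() else 0
    mask = np.zeros(n, dtype=bool)
    mask[order[:k]] = True
    return mask


@dataclass(frozen=True)
class ReplicationReport:
    n_leads: int
    n_nominal: int            # replication p < alpha
    n_fdr: int                # surviving BH at q
    expected_null: int        # round(n_leads * alpha)
    sign_concordant: int | None = None


def assess_replication(replication_p: np.ndarray, alpha: float = 0.05,
                       fdr_q: float = 0.05,
                       discovery_beta: np.ndarray | None = None,
                       replication_beta: np.ndarray | None = None) -> ReplicationReport:
    """Count leads replicating at the nominal level and under BH FDR, with
    the chance expectation round(n x alpha); sign concordance of effect
    estimates is reported as a diagnostic only."""
    p = np.asarray(replication_p, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ParameterError("replication p-values must lie in [0, 1]")
    n = len(p)
    concordant = None
    if discovery_beta is not None and replication_beta is not None:
        concordant = int((np.sign(discovery_beta) == np.sign(replication_beta)).sum())
    return ReplicationReport(
        n_leads=n,
        n_nominal=int((p < alpha).sum()),
        n_fdr=int(benjamini_hochberg(p, q=fdr_q).sum()),
        expected_null=int(round(n * alpha)),
        sign_concordant=concordant,
    )


# ---------------------------------------------------------------------------
# PheWAS
# ---------------------------------------------------------------------------

def phewas_profile(variant: str, assoc_store: pd.DataFrame,
                   threshold: float) -> pd.DataFrame:
    """All phenotypes' -log10 P for one variant, flagged above ``threshold``.

    ``assoc_store`` is a long association table (as from run_mass_gwas); a
    ``group`` column, if present, is carried through for plotting by
    phenotype class.
    """
    rows = assoc_store[assoc_store["variant"] == variant]
    if rows.empty:
        raise KeyError(f"variant {variant!r} not present in the association store")
    cols = ["phenotype", "neglog10_p"] + (["group"] if "group" in rows.columns else [])
    out = rows[cols].copy().reset_index(drop=True)
    out["above_threshold"] = out["neglog10_p"] > threshold
    return out
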