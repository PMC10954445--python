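"""Inferential layers: genotype PCA, Hudson F_ST / PBS selection scan
with downsampling consensus and batch-effect exclusion, cis-eQTL, GWAS
and LD against phenotype-associated SNPs.

Association scans return pandas DataFrames with one row per tested pair
(columns: locus, target, beta, se, p, q/threshold metadata); linear
models share covariates per trait, so dosages and outcomes are
residualized once (Frisch-Waugh) and slopes tested locus-vectorized.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .genotyping import MISSING, GenotypeMatrix, genotype_counts, hwe_exact_test

LAMBDA_GC_NULL_MEDIAN = 0.4549   # median of the chi-square(1) distribution
FST_CLAMP = 1.0 - 1e-9


# ------------------------------------------------------------------ FDR

def bh_fdr(p_values: Sequence[float], q: float
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; returns (significant flags, q-values)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    qvals_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    qvals_sorted = np.clip(qvals_sorted, 0.0, 1.0)
    qvals = np.empty(m)
    qvals[order] = qvals_sorted
    return qvals <= q, qvals


def bonferroni_threshold(alpha: float, m: int) -> tuple[float, str]:
    """alpha/m plus its 2-significant-figure display form."""
    if m <= 0:
        raise ValueError("m must be positive")
    threshold = alpha / m
    display = f"{float(f'{threshold:.1e}'):.1e}"
    return threshold, display


# ------------------------------------------------------------------ PCA

def _dosage_matrix(genotypes: GenotypeMatrix) -> pd.DataFrame:
    return genotypes.dosage.astype(float).replace(MISSING, np.nan)


def locus_maf(genotypes: GenotypeMatrix) -> pd.Series:
    d = _dosage_matrix(genotypes)
    p = d.mean(axis=1) / 2.0
    return pd.Series(np.minimum(p, 1 - p), index=d.index)


def genotype_pca(genotypes: GenotypeMatrix,
                 maf_min: float = 0.05,
                 hwe_p_min: float = 0.0001,
                 n_components: int = 10,
                 ) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the filtered, centred, sqrt(2p(1-p))-scaled dosage matrix.

    Sign convention: each component's largest-magnitude sample loading is
    made positive, so scores are reproducible across sample orderings.
    """
    d = _dosage_matrix(genotypes)
    keep = []
    for locus in d.index:
        row = d.loc[locus]
        p = row.mean() / 2.0
        if min(p, 1 - p) <= maf_min:
            continue
        counts = genotype_counts(genotypes, locus)
        if hwe_exact_test(*counts) < hwe_p_min:
            continue
        keep.append(locus)
    if not keep:
        raise ValueError("no locus passes the MAF/HWE filters")
    sub = d.loc[keep]
    p = sub.mean(axis=1) / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    filled = sub.apply(lambda row: row.fillna(row.mean()), axis=1)
    z = (filled.sub(2.0 * p, axis=0)).div(scale, axis=0).to_numpy()
    if not np.isfinite(z).all() or np.allclose(z, 0.0):
        raise ValueError("genotype matrix carries no variance")
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    n_components = min(n_components, s.size)
    scores = vt[:n_components].T * s[:n_components]
    for c in range(n_components):
        pivot = np.argmax(np.abs(scores[:, c]))
        if scores[pivot, c] < 0:
            scores[:, c] *= -1
    explained = (s ** 2) / (s ** 2).sum()
    frame = pd.DataFrame(scores, index=sub.columns,
                         columns=[f"PC{i + 1}"
                                  for i in range(n_components)])
    return frame, explained[:n_components]


# --------------------------------------------------------------- F_ST / PBS

def hudson_fst(alt1: np.ndarray, n1: np.ndarray,
               alt2: np.ndarray, n2: np.ndarray) -> np.ndarray:
    """Per-locus Hudson F_ST estimator from allele counts.

    N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1);
    D = p1(1-p2) + p2(1-p1); loci with D = 0 come back NaN.
    """
    alt1, n1 = np.asarray(alt1, float), np.asarray(n1, float)
    alt2, n2 = np.asarray(alt2, float), np.asarray(n2, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1, p2 = alt1 / n1, alt2 / n2
        num = ((p1 - p2) ** 2
               - p1 * (1 - p1) / (n1 - 1)
               - p2 * (1 - p2) / (n2 - 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
        fst = np.where(den > 0, num / den, np.nan)
    return fst


def pbs(fst_ab, fst_ac, fst_bc):
    """Population branch statistic for focal population A.

    T = -log(1 - F_ST) with F_ST clamped to [0, 1-1e-9];
    PBS_A = (T_AB + T_AC - T_BC) / 2.
    """
    def branch(f):
        f = np.clip(np.asarray(f, dtype=float), 0.0, FST_CLAMP)
        return -np.log1p(-f)

    value = (branch(fst_ab) + branch(fst_ac) - branch(fst_bc)) / 2.0
    return value if np.ndim(value) else float(value)


def _allele_counts(dosage: pd.DataFrame, samples: Sequence[str]
                   ) -> tuple[np.ndarray, np.ndarray]:
    sub = dosage[list(samples)].to_numpy()
    ok = sub != MISSING
    alt = np.where(ok, sub, 0).sum(axis=1).astype(float)
    n = 2.0 * ok.sum(axis=1)
    return alt, n


def pbs_scan(genotypes: GenotypeMatrix,
             panel: pd.DataFrame,
             focal: str, sister: str, outgroup: str,
             positions: Mapping[str, tuple[str, int]] | None = None,
             maf_min: float = 0.01,
             downsample_to: int = 40,
             replicates: int = 10,
             top_quantile: float = 0.001,
             consensus_min: int = 7,
             merge_window: int = 1_000_000,
             batch_q: pd.Series | None = None,
             seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Downsampling-consensus PBS scan.

    Per replicate the focal population is subsampled without replacement
    to ``downsample_to``; loci whose PBS reaches the top ``top_quantile``
    in at least ``consensus_min`` replicates and pass the batch-effect
    q >= 0.05 bound are candidates, merged into 1 Mb signals represented
    by their maximum mean-PBS locus.
    """
    rng = np.random.default_rng(seed)
    by_pop = {pop: list(panel.loc[(panel["population"] == pop)
                                  & (panel["trio_role"] != "child"),
                                  "sample"])
              for pop in (focal, sister, outgroup)}
    for pop, members in by_pop.items():
        if not members:
            raise ValueError(f"population {pop!r} has no samples")
    dosage = genotypes.dosage
    all_samples = by_pop[focal] + by_pop[sister] + by_pop[outgroup]
    alt_all, n_all = _allele_counts(dosage, all_samples)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_all = alt_all / n_all
    maf = np.minimum(p_all, 1 - p_all)
    polymorphic = (maf > maf_min) & np.isfinite(maf)
    loci = np.array(genotypes.loci)

    alt_s, n_s = _allele_counts(dosage, by_pop[sister])
    alt_o, n_o = _allele_counts(dosage, by_pop[outgroup])
    fst_bc = hudson_fst(alt_s, n_s, alt_o, n_o)

    pbs_reps = np.full((replicates, loci.size), np.nan)
    hit = np.zeros((replicates, loci.size), dtype=bool)
    for rep in range(replicates):
        members = by_pop[focal]
        if len(members) > downsample_to:
            pick = rng.choice(len(members), size=downsample_to,
                              replace=False)
            members = [members[i] for i in sorted(pick)]
        alt_f, n_f = _allele_counts(dosage, members)
        fst_ab = hudson_fst(alt_f, n_f, alt_s, n_s)
        fst_ac = hudson_fst(alt_f, n_f, alt_o, n_o)
        values = pbs(fst_ab, fst_ac, fst_bc)
        values = np.where(polymorphic, values, np.nan)
        pbs_reps[rep] = values
        finite = np.isfinite(values)
        if finite.sum() == 0:
            continue
        cutoff = np.quantile(values[finite], 1.0 - top_quantile)
        hit[rep] = finite & (values >= cutoff)

    hits = hit.sum(axis=0)
    mean_pbs = np.nanmean(pbs_reps, axis=0)
    q = (batch_q.reindex(loci).to_numpy() if batch_q is not None
         else np.ones(loci.size))
    q = np.where(np.isnan(q), 1.0, q)
    candidate = (hits >= consensus_min) & (q >= 0.05)

    result = pd.DataFrame({
        "locus": loci,
        "mean_pbs": mean_pbs,
        "replicate_hits": hits,
        "batch_q": q,
        "candidate": candidate,
        "polymorphic": polymorphic,
    })

    # merge candidates within merge_window into single signals
    signals = []
    if positions is not None and candidate.any():
        cand = result[result["candidate"]].copy()
        cand["chrom"] = [positions[l][0] for l in cand["locus"]]
        cand["position"] = [positions[l][1] for l in cand["locus"]]
        cand = cand.sort_values(["chrom", "position"])
        group_id = 0
        prev_chrom, prev_pos = None, None
        ids = []
        for _, row in cand.iterrows():
            if (row["chrom"] != prev_chrom
                    or row["position"] - prev_pos > merge_window):
                group_id += 1
            ids.append(group_id)
            prev_chrom, prev_pos = row["chrom"], row["position"]
        cand["signal"] = ids
        for sid, group in cand.groupby("signal"):
            best = group.loc[group["mean_pbs"].idxmax()]
            signals.append({
                "signal": int(sid), "locus": best["locus"],
                "chrom": best["chrom"], "position": int(best["position"]),
                "mean_pbs": float(best["mean_pbs"]),
                "n_loci": len(group),
            })
    elif candidate.any():
        for i, locus in enumerate(loci[candidate]):
            signals.append({"signal": i + 1, "locus": locus,
                            "chrom": None, "position": None,
                            "mean_pbs": float(mean_pbs[candidate][i]),
                            "n_loci": 1})
    return result, pd.DataFrame(signals)


def batch_effect_filter(genotypes: GenotypeMatrix,
                        panel: pd.DataFrame) -> pd.Series:
    """BH-corrected per-locus q-value of genotype-by-platform chi-square
    within each multi-platform population (minimum p across populations);
    untestable loci get q = 1."""
    pops = sorted(panel["population"].unique())
    groups = {}
    for pop in pops:
        sub = panel[panel["population"] == pop]
        platforms = sorted(sub["platform"].unique())
        if len(platforms) < 2:
            continue
        groups[pop] = {pl: list(sub.loc[sub["platform"] == pl, "sample"])
                       for pl in platforms}
    p_min = np.ones(len(genotypes.loci))
    testable = np.zeros(len(genotypes.loci), dtype=bool)
    for li, locus in enumerate(genotypes.loci):
        row = genotypes.dosage.loc[locus]
        best = np.nan
        for pop, platforms in groups.items():
            table = []
            for pl, samples in platforms.items():
                values = row[samples].to_numpy()
                values = values[values != MISSING]
                table.append([int((values == g).sum()) for g in (0, 1, 2)])
            table = np.array(table)
            table = table[:, table.sum(axis=0) > 0]
            table = table[table.sum(axis=1) > 0]
            if table.shape[0] < 2 or table.shape[1] < 2:
                continue
            _, p, _, _ = _scipy_stats.chi2_contingency(table)
            best = p if np.isnan(best) else min(best, p)
        if not np.isnan(best):
            p_min[li] = best
            testable[li] = True
    q = np.ones(len(genotypes.loci))
    if testable.any():
        _, qvals = bh_fdr(p_min[testable], 0.05)
        q[testable] = qvals
    return pd.Series(q, index=genotypes.loci)


# ------------------------------------------------------- linear models

def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residuals of y (columns) on [1 | covariates]."""
    n = y.shape[0]
    X = np.column_stack([np.ones(n), covariates]) if covariates.size \
        else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _marginal_tests(y_resid: np.ndarray, G_resid: np.ndarray,
                    df_resid: int) -> tuple[np.ndarray, np.ndarray,
                                            np.ndarray]:
    """Per-column slope, SE and Wald p of y_resid ~ each dosage column."""
    gss = (G_resid ** 2).sum(axis=0)
    gss = np.where(gss > 0, gss, np.nan)
    beta = (G_resid * y_resid[:, None]).sum(axis=0) / gss
    resid_ss = ((y_resid ** 2).sum()
                - beta ** 2 * gss)
    sigma2 = np.clip(resid_ss, 0.0, None) / df_resid
    se = np.sqrt(sigma2 / gss)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * _scipy_stats.t.sf(np.abs(t), df_resid)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return beta, se, p


def cis_eqtl_scan(expression: pd.DataFrame,
                  genotypes: GenotypeMatrix,
                  tss: Mapping[str, tuple[str, int]],
                  positions: Mapping[str, tuple[str, int]],
                  window: int = 1_000_000,
                  maf_min: float = 0.05,
                  drop_multiallelic: bool = True,
                  multiallelic: set[str] | frozenset[str] = frozenset(),
                  covariates: pd.DataFrame | None = None,
                  n_genotype_pcs: int = 5,
                  fdr: float = 0.05) -> pd.DataFrame:
    """Linear cis association of transcript expression with NRS dosage
    within ``window`` of the TSS, BH-corrected across all tested pairs."""
    samples = [s for s in expression.columns if s in genotypes.samples]
    maf = locus_maf(genotypes)
    eligible = [l for l in genotypes.loci
                if maf[l] > maf_min and l in positions
                and not (drop_multiallelic and l in multiallelic)]
    if covariates is None and n_genotype_pcs > 0:
        try:
            scores, _ = genotype_pca(genotypes, maf_min=maf_min,
                                     n_components=n_genotype_pcs)
            covariates = scores.loc[samples]
        except ValueError:
            covariates = None
    C = (covariates.loc[samples].to_numpy()
         if covariates is not None else np.empty((len(samples), 0)))

    d = _dosage_matrix(genotypes)[samples]
    d = d.apply(lambda row: row.fillna(row.mean()), axis=1)
    G_all = _residualize(d.loc[eligible].to_numpy().T, C)
    col_of = {l: i for i, l in enumerate(eligible)}
    n = len(samples)
    df_resid = n - C.shape[1] - 2

    rows = []
    for transcript in expression.index:
        if transcript not in tss:
            continue
        chrom, site = tss[transcript]
        tested = [l for l in eligible
                  if positions[l][0] == chrom
                  and abs(positions[l][1] - site) <= window]
        if not tested:
            continue
        y = expression.loc[transcript, samples].to_numpy(dtype=float)
        y_resid = _residualize(y[:, None], C)[:, 0]
        G = G_all[:, [col_of[l] for l in tested]]
        beta, se, p = _marginal_tests(y_resid, G, df_resid)
        for l, b, s, pv in zip(tested, beta, se, p):
            rows.append({"locus": l, "target": transcript,
                         "beta": b, "se": s, "p": pv, "n": n})
    result = pd.DataFrame(rows)
    if len(result):
        flags, qvals = bh_fdr(result["p"].to_numpy(), fdr)
        result["q"] = qvals
        result["significant"] = flags
    return result


def gwas(genotypes: GenotypeMatrix,
         phenotypes: pd.DataFrame,
         traits: Sequence[str],
         covariate_columns: Sequence[str] = ("age", "sex", "BMI"),
         pcs: pd.DataFrame | None = None,
         n_pcs: int = 2,
         maf_min: float = 0.05,
         model: str = "linear",
         alpha: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Additive-model association of each trait with each passing locus.

    Covariates are age/sex/BMI plus the first ``n_pcs`` genotype PCs; a
    trait also listed as a covariate (BMI) is excluded from its own
    covariate set.  Returns (results, metadata with lambda_GC and the
    Bonferroni threshold).
    """
    if model not in ("linear", "logistic"):
        raise ValueError(f"unknown model {model!r}")
    samples = [s for s in phenotypes.index if s in genotypes.samples]
    maf = locus_maf(genotypes)
    loci = [l for l in genotypes.loci if maf[l] > maf_min]
    if not loci:
        raise ValueError("no locus passes the MAF filter")
    if pcs is None and n_pcs > 0:
        try:
            scores, _ = genotype_pca(genotypes, maf_min=maf_min,
                                     n_components=n_pcs)
            pcs = scores
        except ValueError:
            pcs = None
    d = _dosage_matrix(genotypes)[samples]
    d = d.apply(lambda row: row.fillna(row.mean()), axis=1)
    G_raw = d.loc[loci].to_numpy().T

    rows = []
    chi2_all = []
    for trait in traits:
        cov_cols = [c for c in covariate_columns if c != trait]
        C_parts = [phenotypes.loc[samples, cov_cols].to_numpy(dtype=float)]
        if pcs is not None and n_pcs > 0:
            C_parts.append(pcs.loc[samples].to_numpy()[:, :n_pcs])
        C = np.column_stack(C_parts) if C_parts else np.empty((len(samples), 0))
        y = phenotypes.loc[samples, trait].to_numpy(dtype=float)
        if model == "linear":
            y_resid = _residualize(y[:, None], C)[:, 0]
            G_resid = _residualize(G_raw, C)
            df_resid = len(samples) - C.shape[1] - 2
            beta, se, p = _marginal_tests(y_resid, G_resid, df_resid)
        else:
            import statsmodels.api as sm
            beta = np.empty(len(loci))
            se = np.empty(len(loci))
            p = np.empty(len(loci))
            X_base = np.column_stack([np.ones(len(samples)), C])
            for i in range(len(loci)):
                X = np.column_stack([X_base, G_raw[:, i]])
                try:
                    fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
                    beta[i] = fit.params[-1]
                    se[i] = fit.bse[-1]
                    p[i] = fit.pvalues[-1]
                except Exception:
                    beta[i] = se[i] = p[i] = np.nan
        chi2 = (beta / se) ** 2
        chi2_all.append(chi2[np.isfinite(chi2)])
        for l, b, s, pv in zip(loci, beta, se, p):
            rows.append({"locus": l, "target": trait, "beta": b,
                         "se": s, "p": pv, "n": len(samples)})
    result = pd.DataFrame(rows)
    threshold, display = bonferroni_threshold(alpha, len(loci))
    chi2_all = np.concatenate(chi2_all) if chi2_all else np.array([])
    lambda_gc = (float(np.median(chi2_all) / LAMBDA_GC_NULL_MEDIAN)
                 if chi2_all.size else math.nan)
    result["significant"] = result["p"] <= threshold
    meta = {"lambda_gc": lambda_gc, "bonferroni_threshold": threshold,
            "bonferroni_display": display, "n_loci": len(loci),
            "model": model}
    return result, meta


# ------------------------------------------------------------------- LD

def ld_r2(a: Sequence[float], b: Sequence[float],
          missing_policy: str = "as_ref") -> float:
    """Squared Pearson correlation of dosage vectors.

    Missing entries (negative or NaN) are coded homozygous reference
    (``as_ref``) or dropped pairwise (``pairwise``).  Constant vectors
    give NaN.
    """
    if missing_policy not in ("as_ref", "pairwise"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    miss_x = np.isnan(x) | (x < 0)
    miss_y = np.isnan(y) | (y < 0)
    if missing_policy == "as_ref":
        x = np.where(miss_x, 0.0, x)
        y = np.where(miss_y, 0.0, y)
    else:
        keep = ~(miss_x | miss_y)
        x, y = x[keep], y[keep]
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return math.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_catalogue_scan(nrs_dosage: pd.DataFrame,
                      nrs_positions: Mapping[str, tuple[str, int]],
                      snp_dosage: pd.DataFrame,
                      snp_table: pd.DataFrame,
                      window: int = 100_000,
                      r2_min: float = 0.8,
                      snp_p_max: float = 5e-8,
                      missing_policy: str = "as_ref") -> pd.DataFrame:
    """All (NRS, phenotype-associated SNP) pairs within ``window`` bp
    with r^2 above ``r2_min``; SNPs filtered at ``snp_p_max``."""
    samples = [s for s in nrs_dosage.columns if s in snp_dosage.columns]
    snp_meta = snp_table.set_index("snp")
    rows = []
    for locus in nrs_dosage.index:
        if locus not in nrs_positions:
            continue
        chrom, pos = nrs_positions[locus]
        for snp in snp_dosage.index:
            meta = snp_meta.loc[snp]
            if meta["chrom"] != chrom or meta["p"] > snp_p_max:
                continue
            if abs(int(meta["position"]) - pos) > window:
                continue
            r2 = ld_r2(nrs_dosage.loc[locus, samples],
                       snp_dosage.loc[snp, samples],
                       missing_policy=missing_policy)
            if not math.isnan(r2) and r2 > r2_min:
                rows.append({"locus": locus, "snp": snp, "r2": r2,
                             "snp_p": float(meta["p"]),
                             "distance": abs(int(meta["position"]) - pos)})
    return pd.DataFrame(rows)
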