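"""Candidate-gene association scan with mixed linear models.

The single-marker model is

    y = X beta + s_j alpha_j + u + e,   u ~ N(0, sigma2_g K),  e ~ N(0, sigma2_e I)

with K a genomic kinship matrix.  K is eigendecomposed once; after rotating
by the eigenvectors the covariance is diagonal in the variance ratio
lambda = sigma2_g / sigma2_e, which is profiled by REML under the null model
(no marker).  Each marker is then tested by generalized least squares with
the null variance ratio held fixed (the EMMAX / P3D approximation), using a
Wald F statistic with residual df = N - rank(X) - 1.

CMLM replaces K by its block average over hierarchical clusters of
accessions; MLMM extends the scan stepwise, adding the best marker as a
fixed cofactor and re-estimating variance components each step.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import squareform
from scipy.stats import f as f_dist

from .panel import GenotypePanel, GeneModel, QMatrix, ValidationError

log = logging.getLogger("haplopheno")

MODELS = ("MLM", "CMLM", "MLMM")
RESULT_COLUMNS = ["snp_id", "chrom", "pos", "model", "beta", "se", "p", "pve_pct"]


@dataclass
class KinshipMatrix:
    accession_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.accession_ids)
        if self.values.shape != (n, n):
            raise ValidationError("kinship shape does not match accession list")
        if np.abs(self.values - self.values.T).max() > 1e-10:
            raise ValidationError("kinship must be symmetric")


def kinship(panel: GenotypePanel, method: str = "VANRADEN") -> KinshipMatrix:
    """Genomic kinship from the dosage matrix (het = 1, missing mean-imputed).

    VANRADEN: K = W W' / (2 sum p_j (1 - p_j)) with W the column-centered
    dosage matrix and p_j the alt-allele frequency.  IBS: mean allele-sharing
    proportion, 1 - |d_i - d_j| / 2 averaged over loci.
    """
    d = panel.dosage(impute=True)
    poly = d.std(axis=0) > 0
    if not poly.any():
        raise ValidationError("all loci are monomorphic; kinship undefined")
    d = d[:, poly]
    if method.upper() == "VANRADEN":
        p = d.mean(axis=0) / 2.0
        w = d - 2.0 * p
        denom = 2.0 * np.sum(p * (1.0 - p))
        k = (w @ w.T) / denom
    elif method.upper() == "IBS":
        n = d.shape[0]
        k = np.empty((n, n))
        for i in range(n):
            k[i] = 1.0 - np.abs(d[i] - d).mean(axis=1) / 2.0
        k = (k + k.T) / 2.0
    else:
        raise ValueError("method must be VANRADEN or IBS")
    return KinshipMatrix(accession_ids=list(panel.accession_ids), values=k)


def ld_decay(
    panel: GenotypePanel,
    max_dist_bp: int = 200_000,
    bin_bp: int = 5_000,
    r2_threshold: float = 0.2,
) -> tuple[pd.DataFrame, float | None]:
    """Pairwise r-squared vs distance, binned, plus the LD decay distance.

    r2 is the squared Pearson correlation of dosage vectors for SNP pairs on
    the same chromosome within ``max_dist_bp``; monomorphic pairs are
    skipped.  The decay distance is the midpoint of the first distance bin
    whose mean r2 falls below ``r2_threshold`` (None if no bin does).
    """
    d = panel.dosage(impute=True)
    sd = d.std(axis=0)
    rows = []
    loci = panel.loci
    for i in range(len(loci)):
        if sd[i] == 0:
            continue
        for j in range(i + 1, len(loci)):
            if loci[j].chrom != loci[i].chrom:
                break
            dist = loci[j].pos - loci[i].pos
            if dist > max_dist_bp:
                break
            if sd[j] == 0:
                continue
            r = np.corrcoef(d[:, i], d[:, j])[0, 1]
            rows.append({"snp_a": loci[i].snp_id, "snp_b": loci[j].snp_id,
                         "dist_bp": dist, "r2": r * r})
    pairs = pd.DataFrame(rows, columns=["snp_a", "snp_b", "dist_bp", "r2"])
    decay = None
    if len(pairs):
        bins = (pairs["dist_bp"] // bin_bp).astype(int)
        mean_r2 = pairs.groupby(bins)["r2"].mean().sort_index()
        for b, v in mean_r2.items():
            if v < r2_threshold:
                decay = float((b + 0.5) * bin_bp)
                break
    return pairs, decay


# ---------------------------------------------------------------------------
# Rotated REML machinery
# ---------------------------------------------------------------------------

LOG_LAMBDA_BOUNDS = (-10.0, 10.0)


def _reml_lambda(yr: np.ndarray, Xr: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """Profile REML over lambda in the rotated model; returns (lambda, sigma2_e)."""
    n, p = Xr.shape

    def nll(log_lam: float) -> float:
        lam = math.exp(log_lam)
        d = lam * s + 1.0
        w = 1.0 / d
        Xw = Xr * w[:, None]
        XtWX = Xr.T @ Xw
        XtWy = Xw.T @ yr
        try:
            beta = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError:
            return 1e300
        rss = float(yr @ (w * yr) - beta @ XtWy)
        rss = max(rss, 1e-300)
        sigma2 = rss / (n - p)
        sign, logdet_x = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return 1e300
        return 0.5 * ((n - p) * (math.log(2 * math.pi * sigma2) + 1.0)
                      + float(np.sum(np.log(d))) + logdet_x)

    res = minimize_scalar(nll, bounds=LOG_LAMBDA_BOUNDS, method="bounded",
                          options={"xatol": 1e-8})
    lam = float(math.exp(res.x))
    d = lam * s + 1.0
    w = 1.0 / d
    Xw = Xr * w[:, None]
    beta = np.linalg.solve(Xr.T @ Xw, Xw.T @ yr)
    rss = float(yr @ (w * yr) - beta @ (Xw.T @ yr))
    return lam, rss / (n - p)


def reml_loglik_rotated(y: np.ndarray, X: np.ndarray, K: np.ndarray, lam: float) -> float:
    """REML log-likelihood at a given lambda via the eigen-rotation (profiled sigma2_e)."""
    s, U = np.linalg.eigh(K)
    s = np.clip(s, 0.0, None)
    yr, Xr = U.T @ y, U.T @ X
    n, p = Xr.shape
    d = lam * s + 1.0
    w = 1.0 / d
    Xw = Xr * w[:, None]
    XtWX = Xr.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ yr)
    rss = float(yr @ (w * yr) - beta @ (Xw.T @ yr))
    sigma2 = rss / (n - p)
    _, logdet_x = np.linalg.slogdet(XtWX)
    return -0.5 * ((n - p) * (math.log(2 * math.pi * sigma2) + 1.0)
                   + float(np.sum(np.log(d))) + logdet_x)


def _as_covariate_matrix(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.empty((n, 0))
    if isinstance(covariates, QMatrix):
        return covariates.covariate_design()
    c = np.asarray(covariates, dtype=float)
    return c.reshape(n, -1)


def _align(y: pd.Series, panel: GenotypePanel, K: KinshipMatrix):
    acc = [a for a in panel.accession_ids if a in y.index]
    if len(acc) < 3:
        raise ValidationError("fewer than 3 accessions shared between phenotype and panel")
    if acc != panel.accession_ids:
        panel = panel.subset_accessions(acc)
    if K.accession_ids != acc:
        pos = {a: i for i, a in enumerate(K.accession_ids)}
        try:
            idx = [pos[a] for a in acc]
        except KeyError as exc:
            raise ValidationError(f"accession missing from kinship: {exc}") from exc
        K = KinshipMatrix(acc, K.values[np.ix_(idx, idx)])
    return y.loc[acc].to_numpy(float), panel, K


def _scan_core(
    yv: np.ndarray,
    panel: GenotypePanel,
    K: KinshipMatrix,
    covar: np.ndarray,
    model_tag: str,
    cofactor_idx: list[int] | None = None,
) -> pd.DataFrame:
    """EMMAX-style scan: null REML for lambda, then vectorized GLS per SNP."""
    n = len(yv)
    G = panel.dosage(impute=True)
    X0 = np.column_stack([np.ones(n), covar])
    if cofactor_idx:
        X0 = np.column_stack([X0, G[:, cofactor_idx]])
    if np.linalg.matrix_rank(X0) < X0.shape[1]:
        raise ValidationError("covariate design is singular")
    s, U = np.linalg.eigh(K.values)
    s = np.clip(s, 0.0, None)
    yr, X0r, Gr = U.T @ yv, U.T @ X0, U.T @ G
    lam, _ = _reml_lambda(yr, X0r, s)

    w = 1.0 / (lam * s + 1.0)
    p = X0r.shape[1]
    dfe = n - p - 1
    if dfe < 1:
        raise ValidationError("not enough residual degrees of freedom")
    X0w = X0r * w[:, None]
    A00 = X0r.T @ X0w                      # p x p
    a0y = X0w.T @ yr                       # p
    A0g = X0w.T @ Gr                       # p x M
    agg = np.einsum("ij,i,ij->j", Gr, w, Gr)
    agy = Gr.T @ (w * yr)
    yy = float(yr @ (w * yr))
    A00_inv = np.linalg.inv(A00)
    c = A00_inv @ a0y
    B = A00_inv @ A0g
    denom = agg - np.einsum("ij,ij->j", A0g, B)
    num = agy - A0g.T @ c
    rss0 = yy - float(a0y @ c)

    var_y = float(np.var(yv))
    snp_var = G.var(axis=0)
    ok = denom > max(1e-9, 1e-9 * float(np.max(np.abs(agg)) or 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(ok, num / denom, np.nan)
        rss = rss0 - np.where(ok, num**2 / denom, 0.0)
        sigma2 = np.maximum(rss, 0.0) / dfe
        se = np.sqrt(np.where(ok, sigma2 / denom, np.nan))
        fstat = np.where(ok & (sigma2 > 0), alpha**2 * denom / sigma2, np.nan)
        pvals = np.where(np.isnan(fstat), np.nan, f_dist.sf(fstat, 1, dfe))
        pve = np.where(ok, 100.0 * snp_var * alpha**2 / var_y if var_y > 0 else np.nan, np.nan)
    # monomorphic SNPs are flagged NA, not dropped
    mono = snp_var == 0
    for arr in (alpha, se, pvals, pve):
        arr[mono] = np.nan

    return pd.DataFrame(
        {
            "snp_id": panel.snp_ids,
            "chrom": [l.chrom for l in panel.loci],
            "pos": [l.pos for l in panel.loci],
            "model": model_tag,
            "beta": alpha,
            "se": se,
            "p": pvals,
            "pve_pct": pve,
        }
    )


def mlm_scan(
    y: pd.Series,
    panel: GenotypePanel,
    K: KinshipMatrix,
    covariates: QMatrix | np.ndarray | None = None,
) -> pd.DataFrame:
    """Single-marker mixed linear model scan.

    ``y`` is a per-accession phenotype (typically a combined stress BLUP)
    indexed by accession id; ``covariates`` is usually the Q matrix (one
    column is dropped internally for identifiability).  Returns one row per
    SNP with columns snp_id, chrom, pos, model, beta, se, p, pve_pct;
    monomorphic SNPs carry NaNs.
    """
    yv, panel, K = _align(y, panel, K)
    covar = _as_covariate_matrix(covariates, len(yv))
    return _scan_core(yv, panel, K, covar, "MLM")


def compress_kinship(K: KinshipMatrix, n_groups: int) -> tuple[KinshipMatrix, np.ndarray]:
    """Average-linkage clustering on (1 - K) distance; block-averaged kinship."""
    n = len(K.accession_ids)
    if not (1 <= n_groups <= n):
        raise ValidationError("n_groups must be between 1 and N")
    if n_groups == n:
        return K, np.arange(n)
    dist = 1.0 - K.values
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="average")
    groups = fcluster(z, t=n_groups, criterion="maxclust") - 1
    k_grp = np.zeros((n_groups, n_groups))
    counts = np.bincount(groups, minlength=n_groups).astype(float)
    for a in range(n_groups):
        ia = groups == a
        for b in range(a, n_groups):
            ib = groups == b
            v = K.values[np.ix_(ia, ib)].mean()
            k_grp[a, b] = k_grp[b, a] = v
    expanded = k_grp[np.ix_(groups, groups)]
    return KinshipMatrix(list(K.accession_ids), expanded), groups


def cmlm_scan(
    y: pd.Series,
    panel: GenotypePanel,
    K: KinshipMatrix,
    covariates: QMatrix | np.ndarray | None = None,
    n_groups: int | None = None,
) -> pd.DataFrame:
    """Compressed MLM: accessions clustered, group-mean kinship replaces K."""
    yv, panel, K = _align(y, panel, K)
    if n_groups is None:
        n_groups = math.ceil(len(yv) / 10)
    if n_groups == 0:
        raise ValidationError("n_groups must be >= 1")
    K_c, _ = compress_kinship(K, n_groups)
    covar = _as_covariate_matrix(covariates, len(yv))
    return _scan_core(yv, panel, K_c, covar, "CMLM")


def mlmm_scan(
    y: pd.Series,
    panel: GenotypePanel,
    K: KinshipMatrix,
    covariates: QMatrix | np.ndarray | None = None,
    max_steps: int = 5,
    add_threshold: float = 0.005,
) -> pd.DataFrame:
    """Multi-locus MLM: forward stepwise cofactor selection.

    Each step scans all markers, then adds the lowest-p marker as a fixed
    cofactor when its p-value passes ``add_threshold``, re-estimating the
    variance ratio; stops at ``max_steps`` or when no marker qualifies.  A
    marker's reported p-value comes from the step before its inclusion (or
    the final scan if never included).
    """
    yv, panel, K = _align(y, panel, K)
    covar = _as_covariate_matrix(covariates, len(yv))
    selected: list[int] = []
    frozen: dict[int, pd.Series] = {}
    scan = _scan_core(yv, panel, K, covar, "MLMM", cofactor_idx=None)
    for _ in range(max_steps):
        open_p = scan["p"].copy()
        open_p.iloc[selected] = np.nan
        if open_p.isna().all():
            break
        best = int(open_p.idxmin())
        if not (open_p.loc[best] <= add_threshold):
            break
        frozen[best] = scan.iloc[best]
        selected.append(best)
        scan = _scan_core(yv, panel, K, covar, "MLMM", cofactor_idx=selected)
    # cofactors themselves have no test in the final scan; restore frozen rows
    out = scan.copy()
    for idx, row in frozen.items():
        out.iloc[idx] = row
    return out


@dataclass
class MtaSet:
    """Markers significant in every configured model, with candidate genes."""

    table: pd.DataFrame  # snp_id, chrom, pos, p_<model>..., candidate_genes, status
    threshold: float
    models: list[str]

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    def chromosome_tally(self) -> pd.Series:
        return self.table.groupby("chrom").size().sort_index()


def select_mtas(results: list[pd.DataFrame], threshold: float = 0.005) -> MtaSet:
    """Intersection over models of markers with p <= threshold.

    A marker with a missing p-value in any model (monomorphic flag) fails the
    intersection.  Bonferroni-adjusted p-values are carried as extra columns
    for reference only; selection uses the raw threshold rule.
    """
    if not results:
        raise ValidationError("select_mtas needs at least one model result")
    models = [df["model"].iloc[0] for df in results]
    base = results[0][["snp_id", "chrom", "pos"]].copy()
    keep = np.ones(len(base), dtype=bool)
    for df, tag in zip(results, models):
        df = df.set_index("snp_id").loc[base["snp_id"]]
        p = df["p"].to_numpy(float)
        base[f"p_{tag}"] = p
        m = int(np.isfinite(p).sum())
        base[f"p_{tag}_bonferroni"] = np.minimum(p * max(m, 1), 1.0)
        keep &= np.isfinite(p) & (p <= threshold)
    table = base[keep].reset_index(drop=True)
    table["candidate_genes"] = ""
    table["status"] = ""
    return MtaSet(table=table, threshold=threshold, models=models)


def annotate_candidates(
    mtas: MtaSet, genes: list[GeneModel], window_bp: int = 50_000
) -> MtaSet:
    """Assign each MTA to every gene whose span padded by ``window_bp`` contains it.

    ``status`` records genic (inside the unpadded span) vs flanking.
    """
    table = mtas.table.copy()
    gene_lists, statuses = [], []
    for _, row in table.iterrows():
        pos0 = int(row["pos"]) - 1
        hits, status = [], ""
        for g in genes:
            if g.chrom != str(row["chrom"]):
                continue
            if g.start - window_bp <= pos0 < g.end + window_bp:
                hits.append(g.gene_id)
                if g.start <= pos0 < g.end:
                    status = "genic"
                elif not status:
                    status = "flanking"
        gene_lists.append(";".join(hits))
        statuses.append(status)
    table["candidate_genes"] = gene_lists
    table["status"] = statuses
    return MtaSet(table=table, threshold=mtas.threshold, models=mtas.models)
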