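"""Mixed-model phenotype analysis for the augmented field trial.

Per season x condition the plot model is

    y = mu + block (fixed) + genotype (random, variance sigma2_g) + e

with e ~ N(0, sigma2_e).  REML is maximised by a 1-D Brent search over the
profiled variance ratio lambda = sigma2_g / sigma2_e on log lambda in
[-10, 10]; with records grouped by genotype the marginal covariance
V = I + lambda Z Z' is block diagonal, so every likelihood evaluation is
O(n) via the Woodbury identity.  BLUPs are the shrinkage predictors from the
mixed-model equations, reported on the phenotype scale (fitted mean + u_hat).

Derived statistics follow standard plant-breeding definitions: genotypic
coefficient of variation GCV% = 100 sqrt(sigma2_g) / mean; entry-mean
repeatability H% = 100 sigma2_g / (sigma2_g + sigma2_e / r); genetic advance
as percent of mean GAM% = 100 k (H/100) sqrt(sigma2_g + sigma2_e / r) / mean
with selection differential k (default 2.06, 5% selection intensity).

The drought susceptibility index is the classical Fischer-Maurer form
DSI_i = (1 - Ys_i / Yp_i) / (1 - mean(Ys) / mean(Yp)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .panel import PhenotypeTable, ValidationError

log = logging.getLogger("haplopheno")

LOG_LAMBDA_BOUNDS = (-10.0, 10.0)


class SingularDesignError(ValidationError):
    """Fixed-effect design is rank deficient (e.g. block confounded with one genotype)."""


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    grand_mean: float
    n_reps: float  # harmonic-mean replicates per genotype
    df_error: int
    log_reml: float = float("nan")

    def __post_init__(self) -> None:
        if self.sigma2_g < 0:
            raise ValidationError("sigma2_g must be >= 0")


@dataclass
class VariabilityStats:
    gcv_pct: float
    repeatability_pct: float
    gam_pct: float
    selection_intensity_k: float = 2.06


def _design(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Return (y, X fixed design, genotype codes, genotype level names)."""
    y = df["spy_grams"].to_numpy(float)
    geno, levels = pd.factorize(df["accession_id"], sort=True)
    blocks = pd.factorize(df["block"], sort=True)[0]
    n = len(y)
    n_blocks = blocks.max() + 1
    X = [np.ones(n)]
    for b in range(1, n_blocks):  # drop-first block dummies
        X.append((blocks == b).astype(float))
    X = np.column_stack(X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError("block design is rank deficient")
    return y, X, geno, list(levels)


def fit_reml(
    pheno: PhenotypeTable, season: str, condition: str
) -> tuple[VarianceComponents, pd.Series]:
    """REML variance components and per-accession BLUPs for one season x condition.

    Returns the components and a Series of BLUPs on the phenotype scale
    (fitted population mean + genotype effect), indexed by accession.
    """
    df = pheno.subset(season=season, condition=condition)
    if df.empty:
        raise ValidationError(f"no records for season={season}, condition={condition}")
    y, X, geno, levels = _design(df)
    n, p = X.shape
    G = len(levels)
    if G < 2:
        raise ValidationError("need at least two accessions")
    if n - p <= 0:
        raise SingularDesignError("no residual degrees of freedom")
    counts = np.bincount(geno, minlength=G).astype(float)

    ybar = float(np.mean(y))
    if np.ptp(y) == 0.0:
        # degenerate: literally no variation anywhere
        vc = VarianceComponents(0.0, 0.0, ybar, _harmonic_mean(counts), n - p, 0.0)
        return vc, pd.Series(ybar, index=pd.Index(levels, name="accession_id"), name="blup")

    def vinv_mul(lam: float, a: np.ndarray) -> np.ndarray:
        """(I + lam Z Z')^{-1} a via Woodbury; a is (n,) or (n, k)."""
        w = lam / (1.0 + lam * counts)  # per-genotype shrink weight
        if a.ndim == 1:
            gs = np.zeros(G)
            np.add.at(gs, geno, a)
            return a - w[geno] * gs[geno]
        gs = np.zeros((G, a.shape[1]))
        np.add.at(gs, geno, a)
        return a - w[geno, None] * gs[geno]

    def profile(log_lam: float) -> tuple[float, np.ndarray, float]:
        """Negative REML log-likelihood profiled over sigma2_e, plus beta, rss."""
        lam = float(np.exp(log_lam))
        ViX = vinv_mul(lam, X)
        Viy = vinv_mul(lam, y)
        XtViX = X.T @ ViX
        XtViy = X.T @ Viy
        try:
            beta = np.linalg.solve(XtViX, XtViy)
        except np.linalg.LinAlgError as exc:
            raise SingularDesignError("X' V^{-1} X is singular") from exc
        rss = float(y @ Viy - beta @ XtViy)
        rss = max(rss, 1e-300)
        sigma2_e = rss / (n - p)
        logdet_v = float(np.sum(np.log1p(lam * counts)))
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            raise SingularDesignError("X' V^{-1} X not positive definite")
        nll = 0.5 * (
            (n - p) * (np.log(2.0 * np.pi * sigma2_e) + 1.0) + logdet_v + logdet_x
        )
        return nll, beta, rss

    res = minimize_scalar(
        lambda t: profile(t)[0],
        bounds=LOG_LAMBDA_BOUNDS,
        method="bounded",
        options={"xatol": 1e-9},
    )
    if not res.success:
        raise ValidationError(f"REML did not converge: {res.message}")
    log_lam = float(res.x)
    lam = float(np.exp(log_lam))
    nll, beta, rss = profile(log_lam)
    sigma2_e = rss / (n - p)
    # at the lower search bound the ratio is numerically zero
    at_floor = log_lam <= LOG_LAMBDA_BOUNDS[0] + 1e-6
    sigma2_g = 0.0 if at_floor else lam * sigma2_e

    resid = y - X @ beta
    w = lam / (1.0 + lam * counts)
    gs = np.zeros(G)
    np.add.at(gs, geno, resid)
    u = lam * (gs - w * counts * gs)  # lam * Z' V^{-1} r, grouped form
    if at_floor:
        u = np.zeros(G)
    fitted_mean = float(np.mean(X @ beta))
    blups = pd.Series(
        fitted_mean + u, index=pd.Index(levels, name="accession_id"), name="blup"
    )
    vc = VarianceComponents(
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        grand_mean=ybar,
        n_reps=_harmonic_mean(counts),
        df_error=n - p,
        log_reml=-nll,
    )
    return vc, blups


def _harmonic_mean(counts: np.ndarray) -> float:
    return float(len(counts) / np.sum(1.0 / counts))


def variability_stats(
    vc: VarianceComponents, k: float = 2.06, r: float | None = None
) -> VariabilityStats:
    """GCV%, entry-mean repeatability% and GAM% from fitted components."""
    if vc.grand_mean <= 0:
        raise ValidationError("grand mean must be positive for scale-relative statistics")
    r = vc.n_reps if r is None else r
    phen_var = vc.sigma2_g + vc.sigma2_e / r
    gcv = 100.0 * np.sqrt(vc.sigma2_g) / vc.grand_mean
    h = vc.sigma2_g / phen_var if phen_var > 0 else 0.0
    gam = 100.0 * k * h * np.sqrt(phen_var) / vc.grand_mean
    return VariabilityStats(
        gcv_pct=float(gcv),
        repeatability_pct=float(100.0 * h),
        gam_pct=float(gam),
        selection_intensity_k=k,
    )


def combine_blups(blups_by_season: dict[str, pd.Series]) -> pd.DataFrame:
    """Arithmetic mean of per-season BLUPs per accession.

    Accessions missing a season use the seasons they have and are flagged
    (``n_seasons`` < number of seasons supplied).
    """
    if not blups_by_season:
        raise ValidationError("no season BLUPs supplied")
    wide = pd.DataFrame(blups_by_season)
    out = pd.DataFrame(
        {
            "combined_blup": wide.mean(axis=1, skipna=True),
            "n_seasons": wide.notna().sum(axis=1),
        }
    )
    out = out[out["n_seasons"] > 0]
    partial = int((out["n_seasons"] < len(blups_by_season)).sum())
    if partial:
        log.warning("combine_blups: %d accessions missing at least one season", partial)
    out.index.name = "accession_id"
    return out


def dsi(blups_stress: pd.Series, blups_nonstress: pd.Series) -> pd.Series:
    """Fischer-Maurer drought susceptibility index per accession.

    DSI_i = (1 - Ys_i/Yp_i) / D with D = 1 - mean(Ys)/mean(Yp) over the
    paired panel.  DSI 1 means average susceptibility, 0 means no yield loss.
    Accessions with non-positive non-stress yield are excluded with a warning.
    """
    paired = pd.DataFrame({"ys": blups_stress, "yp": blups_nonstress}).dropna()
    bad = paired.index[paired["yp"] <= 0]
    if len(bad):
        log.warning("dsi: excluding %d accessions with non-positive control yield", len(bad))
        paired = paired.drop(bad)
    if paired.empty:
        raise ValidationError("no valid paired accessions for DSI")
    d = 1.0 - paired["ys"].mean() / paired["yp"].mean()
    if d <= 0:
        raise ValidationError(
            "panel mean yield under stress is not below non-stress; DSI undefined"
        )
    out = (1.0 - paired["ys"] / paired["yp"]) / d
    out.name = "dsi"
    return out
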