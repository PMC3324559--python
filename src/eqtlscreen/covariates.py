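"""Covariate construction for the eQTL and GWAS models.

Expression heterogeneity from unmodelled technical or demographic factors
(batch, cell composition, environment) is captured by surrogate variables: a
two-step procedure that regresses each probe on the known covariates, takes
the SVD of the residual matrix, and keeps the components whose variance share
survives a Buja-Eyuboglu permutation test.  Disease status is protected by
including it among the known covariates when forming residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class CovariateSet:
    """Labelled design matrices for the two model families."""

    gwas: pd.DataFrame  # sex + cohort dummies + selected genotype PCs
    eqtl: pd.DataFrame  # status + age + sex + riluzole + surrogate variables
    selected_pcs: list


def estimate_surrogate_variables(
    expr: pd.DataFrame,
    known_covariates: pd.DataFrame,
    n_perm: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Estimate surrogate variables from the expression residual matrix.

    Each probe is regressed on the known covariates (plus intercept); the
    residual matrix (samples x probes) is decomposed by SVD.  For each
    component index k, the observed variance share is compared with its
    distribution when every probe's residuals are independently permuted
    (``n_perm`` rounds); components are kept while their permutation p-value
    (add-one estimator) stays at or below ``alpha``.  Returns the orthonormal
    sample loadings of the significant components (possibly zero columns).
    """
    rng = np.random.default_rng([seed, 37])
    Y = expr.to_numpy(dtype=float)
    n = Y.shape[0]
    C = _with_intercept(known_covariates.loc[expr.index])
    _check_full_rank(C)
    Q, _ = np.linalg.qr(C.to_numpy(dtype=float))
    R = Y - Q @ (Q.T @ Y)

    k_max = min(n - C.shape[1], R.shape[1]) - 1
    if k_max < 1:
        return pd.DataFrame(index=expr.index)
    obs_share = _variance_shares(R, k_max)
    perm_shares = np.empty((n_perm, k_max))
    for b in range(n_perm):
        Rp = _permute_columns(R, rng)
        Rp = Rp - Q @ (Q.T @ Rp)  # re-residualize so shares are comparable
        perm_shares[b] = _variance_shares(Rp, k_max)

    keep = 0
    for k in range(k_max):
        exceed = int((perm_shares[:, k] >= obs_share[k]).sum())
        p = (1 + exceed) / (1 + n_perm)
        if p <= alpha:
            keep += 1
        else:
            break
    U, S, _ = np.linalg.svd(R, full_matrices=False)
    sv = U[:, :keep]
    return pd.DataFrame(
        sv, index=expr.index, columns=[f"SV{i + 1}" for i in range(keep)]
    )


def _variance_shares(R: np.ndarray, k: int) -> np.ndarray:
    s = np.linalg.svd(R, compute_uv=False)
    share = s**2 / (s**2).sum()
    return share[:k]


def _permute_columns(R: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(R)
    n = R.shape[0]
    for j in range(R.shape[1]):
        out[:, j] = R[rng.permutation(n), j]
    return out


def _with_intercept(C: pd.DataFrame) -> pd.DataFrame:
    if "const" not in C.columns:
        C = C.copy()
        C.insert(0, "const", 1.0)
    return C


def _check_full_rank(C: pd.DataFrame) -> None:
    X = C.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via QR pivoting on the correlation pattern
        bad = []
        for j in range(X.shape[1]):
            sub = X[:, [c for c in range(X.shape[1]) if c != j]]
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(C.columns[j])
        raise ValueError(f"known covariates are collinear; involved columns: {bad}")


def assemble_covariates(
    pheno: pd.DataFrame,
    pcs: pd.DataFrame,
    svs: pd.DataFrame | None = None,
    pc_select_p: float = 0.05,
    n_pcs_tested: int = 10,
) -> CovariateSet:
    """Build the GWAS and eQTL covariate sets.

    GWAS: sex + cohort dummies + every one of the top ``n_pcs_tested``
    genotype PCs individually associated with case/control status at
    ``p < pc_select_p`` (univariate logistic regression).  eQTL: status,
    age, sex, riluzole use, plus the surrogate variables.
    """
    common = pheno.index.intersection(pcs.index)
    if len(common) < len(pheno.index) or len(common) < len(pcs.index):
        offenders = list(pheno.index.symmetric_difference(pcs.index))[:5]
        raise ValueError(f"sample id mismatch between phenotypes and PCs: {offenders}")
    pcs = pcs.loc[pheno.index]
    status = pheno["status"].to_numpy(dtype=float)

    selected = []
    for col in pcs.columns[:n_pcs_tested]:
        x = sm.add_constant(pcs[[col]].to_numpy(dtype=float))
        try:
            fit = sm.Logit(status, x).fit(disp=0)
            p = fit.pvalues[1]
        except Exception:
            p = 1.0
        if p < pc_select_p:
            selected.append(col)

    gwas = pd.DataFrame(index=pheno.index)
    gwas["sex"] = pheno["sex"].astype(float)
    if "cohort" in pheno.columns:
        dummies = pd.get_dummies(pheno["cohort"], prefix="cohort", drop_first=True)
        for c in dummies.columns:
            gwas[c] = dummies[c].astype(float)
    for col in selected:
        gwas[col] = pcs[col].astype(float)

    eqtl = pd.DataFrame(index=pheno.index)
    for col in ("status", "age", "sex", "riluzole"):
        if col in pheno.columns:
            eqtl[col] = pheno[col].astype(float)
    if svs is not None and svs.shape[1]:
        for c in svs.columns:
            eqtl[c] = svs.loc[pheno.index, c].astype(float)

    return CovariateSet(gwas=gwas, eqtl=eqtl, selected_pcs=selected)
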