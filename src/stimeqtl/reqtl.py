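"""Response-eQTL detection: genotype x condition interaction in a linear
mixed model with a within-individual permutation null.

The model for a combined resting+stimulated cell-type dataset is

``y ~ x + c + x*c + x1..x14 + x1*c..x14*c + (1 | individual)``

with x the allele dosage, c the condition indicator (resting 0,
stimulated 1) and a random intercept per individual for the paired design.
The interaction coefficient's Wald z is compared against a permutation
distribution in which each individual's condition labels are swapped (or
not) independently, preserving covariates and pairing exactly; the
empirical p-value is (s + 1)/(n + 1).

The mixed model is fit by profiled REML over the single variance ratio
(random-intercept over residual variance), reduced to a one-dimensional
optimisation with closed-form GLS at each step. This keeps a permutation
refit at ~1 ms so the full null is affordable; the fit is cross-checked
against statsmodels' MixedLM in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .cis import bh_fdr
from .data import GenotypePanel, ExpressionStudy

logger = logging.getLogger("stimeqtl")


# ---------------------------------------------------------------------------
# random-intercept linear mixed model (profiled REML)
# ---------------------------------------------------------------------------

class RandomInterceptLMM:
    """REML fit of y = Xb + u[group] + e with a scalar variance ratio.

    Precomputes the group structure; ``fit`` returns the coefficient
    vector, standard errors and the REML variance components. Falls back
    to OLS with individual fixed effects (within transformation) when the
    variance structure degenerates.
    """

    def __init__(self, groups: np.ndarray):
        self.groups, self.group_index = np.unique(groups, return_inverse=True)
        self.n_groups = len(self.groups)
        self.k = np.bincount(self.group_index).astype(float)

    def _group_sum(self, m: np.ndarray) -> np.ndarray:
        out = np.zeros((self.n_groups,) + m.shape[1:])
        np.add.at(out, self.group_index, m)
        return out

    def fit(self, X: np.ndarray, y: np.ndarray):
        n, p = X.shape
        if n <= p:
            raise ValueError("more parameters than samples")
        XtX = X.T @ X
        Xty = X.T @ y
        yty = float(y @ y)
        S = self._group_sum(X)           # (G x p)
        q = self._group_sum(y)           # (G,)
        k = self.k
        dof = n - p

        def profile(lam: float):
            c = lam / (1.0 + lam * k)
            XtWX = XtX - S.T @ (c[:, None] * S)
            XtWy = Xty - S.T @ (c * q)
            yWy = yty - float(c @ q ** 2)
            try:
                L = np.linalg.cholesky(XtWX)
            except np.linalg.LinAlgError:
                return None
            beta = np.linalg.solve(XtWX, XtWy)
            rss = max(yWy - float(beta @ XtWy), 0.0)
            sigma2 = rss / dof
            logdet_v = float(np.log1p(lam * k).sum())
            logdet_x = 2.0 * float(np.log(np.diag(L)).sum())
            crit = logdet_v + logdet_x + dof * np.log(max(sigma2, 1e-300))
            return crit, beta, sigma2, XtWX

        def objective(log_lam: float) -> float:
            res = profile(np.exp(log_lam))
            return np.inf if res is None else res[0]

        opt = minimize_scalar(objective, bounds=(np.log(1e-8), np.log(1e4)),
                              method="bounded",
                              options={"xatol": 1e-3})
        lam = float(np.exp(opt.x))
        res = profile(lam)
        if res is None or res[2] <= 0:
            raise np.linalg.LinAlgError("singular fixed-effect design")
        _, beta, sigma2, XtWX = res
        cov = sigma2 * np.linalg.inv(XtWX)
        se = np.sqrt(np.diag(cov))
        return beta, se, sigma2, lam * sigma2


def _within_ols(X: np.ndarray, y: np.ndarray, group_index: np.ndarray,
                col: int) -> tuple[float, float, float]:
    """OLS with individual fixed effects (within-demeaned); fallback path."""
    def demean(m):
        g_mean = np.zeros((group_index.max() + 1,) + m.shape[1:])
        counts = np.bincount(group_index).astype(float)
        np.add.at(g_mean, group_index, m)
        g_mean = (g_mean.T / counts).T
        return m - g_mean[group_index]
    Xd, yd = demean(X), demean(y)
    keep = Xd.std(axis=0) > 1e-12
    coef, *_ = np.linalg.lstsq(Xd[:, keep], yd, rcond=None)
    resid = yd - Xd[:, keep] @ coef
    dof = len(yd) - keep.sum() - len(np.unique(group_index))
    sigma2 = float(resid @ resid) / max(dof, 1)
    cov = sigma2 * np.linalg.inv(Xd[:, keep].T @ Xd[:, keep])
    pos = int(keep[:col].sum())
    return float(coef[pos]), float(np.sqrt(cov[pos, pos])), float(dof)


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------

@dataclass
class ReqtlDesign:
    """Stacked two-condition design for one gene/SNP interaction test."""

    y: np.ndarray
    dosage: np.ndarray
    condition: np.ndarray      # 0 resting, 1 stimulated
    covariates: np.ndarray     # n x 14
    individual: np.ndarray

    def __post_init__(self) -> None:
        if not np.isin(self.condition, [0, 1]).all():
            raise ValueError("condition must be coded 0/1")
        pairs = pd.crosstab(self.individual, self.condition)
        if (pairs.to_numpy() > 1).any():
            raise ValueError("an individual contributes >1 sample per condition")

    def design_matrix(self, condition: np.ndarray | None = None
                      ) -> tuple[np.ndarray, int]:
        """Full fixed-effect matrix; returns (X, interaction column index)."""
        c = self.condition if condition is None else condition
        cols = [np.ones(len(self.y)), self.dosage, c, self.dosage * c]
        inter_idx = 3
        cols.append(self.covariates)
        cols.append(self.covariates * c[:, None])
        X = np.column_stack(cols)
        return X, inter_idx


def build_design(study: ExpressionStudy, panel: GenotypePanel, gene: str,
                 snp: str, cell_type: str) -> ReqtlDesign:
    """Assemble the combined resting+stimulated design for one cell type."""
    sheets = study.samples[study.samples["cell_type"] == cell_type]
    conds = sheets["condition"].unique()
    ys, gs, cs, covs, inds = [], [], [], [], []
    for cond in conds:
        expr = study.expression[cond]
        sheet = sheets[sheets["condition"] == cond].loc[expr.index]
        stim = 0.0 if (sheet["treatment"] == "resting").all() else 1.0
        ys.append(expr[gene].to_numpy(float))
        gs.append(panel.dosages.loc[sheet["individual"], snp].to_numpy(float))
        cs.append(np.full(len(sheet), stim))
        covs.append(sheet[study.covariate_columns].to_numpy(float))
        inds.append(sheet["individual"].to_numpy())
    return ReqtlDesign(y=np.concatenate(ys), dosage=np.concatenate(gs),
                       condition=np.concatenate(cs),
                       covariates=np.vstack(covs),
                       individual=np.concatenate(inds))


# ---------------------------------------------------------------------------
# interaction fit + permutation null
# ---------------------------------------------------------------------------

def fit_interaction_lmm(design: ReqtlDesign,
                        condition: np.ndarray | None = None,
                        lmm: RandomInterceptLMM | None = None
                        ) -> tuple[float, float, float]:
    """Interaction (x*c) coefficient, SE and Wald z for one design.

    REML random-intercept fit; degenerate variance structures fall back to
    OLS with individual fixed effects (logged).
    """
    lmm = RandomInterceptLMM(design.individual) if lmm is None else lmm
    X, j = design.design_matrix(condition)
    try:
        beta, se, _, _ = lmm.fit(X, design.y)
        return float(beta[j]), float(se[j]), float(beta[j] / se[j])
    except np.linalg.LinAlgError:
        logger.warning("LMM degenerate; falling back to within-individual OLS")
        b, s, _ = _within_ols(X, design.y, lmm.group_index, j)
        return b, s, b / s


def permute_condition_within_individual(design: ReqtlDesign,
                                        n_perm: int = 1000, seed: int = 0,
                                        early_stop_s: int | None = 50
                                        ) -> dict:
    """Empirical interaction p-value from within-individual label swaps.

    Each permutation flips (or not) every individual's full condition
    pair, preserving covariates and pairing; the model is refit and the
    count s of permuted \\|z\\| >= observed \\|z\\| gives
    p_emp = (s + 1)/(n + 1). Individuals observed in only one condition
    keep their label (no swap possible). With ``early_stop_s`` set,
    permutation stops once s reaches it (the p-value can no longer reach
    significance); the denominator then uses the permutations performed.
    """
    rng = np.random.default_rng(seed)
    lmm = RandomInterceptLMM(design.individual)
    beta, se, z_obs = fit_interaction_lmm(design, lmm=lmm)

    gi = lmm.group_index
    n_cond_per_ind = np.zeros(lmm.n_groups)
    np.add.at(n_cond_per_ind, gi, np.ones(len(gi)))
    swappable = n_cond_per_ind > 1
    if not swappable.all():
        logger.info("%d individuals observed in one condition only; "
                    "their labels are fixed", int((~swappable).sum()))

    s = 0
    done = 0
    for _ in range(n_perm):
        flip = rng.random(lmm.n_groups) < 0.5
        flip &= swappable
        c_perm = np.where(flip[gi], 1.0 - design.condition, design.condition)
        _, _, z = fit_interaction_lmm(design, condition=c_perm, lmm=lmm)
        done += 1
        if abs(z) >= abs(z_obs):
            s += 1
        if early_stop_s is not None and s >= early_stop_s:
            break
    p_emp = (s + 1) / (done + 1)
    return {"beta": beta, "se": se, "z": z_obs, "s": s, "n_perm": done,
            "p_emp": p_emp}


# ---------------------------------------------------------------------------
# test selection and FDR
# ---------------------------------------------------------------------------

def select_reqtl_tests(egenes_resting: pd.DataFrame,
                       egenes_stimulated: pd.DataFrame,
                       panel: GenotypePanel,
                       r2_thresh: float = 0.8) -> pd.DataFrame:
    """Choose the eGene/top-eSNP pairs to interaction-test in a cell type.

    Genes significant in one condition contribute that condition's top
    eSNP; genes significant in both contribute both top eSNPs when they
    are not in high LD (r^2 < ``r2_thresh``), otherwise only the one from
    the condition with the smaller locally adjusted p.
    """
    er = egenes_resting[egenes_resting["egene"].astype(bool)].set_index("gene")
    es = egenes_stimulated[
        egenes_stimulated["egene"].astype(bool)].set_index("gene")
    rows = []
    for gene in er.index.union(es.index):
        in_r, in_s = gene in er.index, gene in es.index
        if in_r and in_s:
            snp_r, snp_s = er.loc[gene, "top_snp"], es.loc[gene, "top_snp"]
            if snp_r == snp_s or panel.ld_r2(snp_r, snp_s) >= r2_thresh:
                best = snp_r if er.loc[gene, "p_local"] <= es.loc[gene, "p_local"] \
                    else snp_s
                rows.append({"gene": gene, "snp": best, "source": "both_ld"})
            else:
                rows.append({"gene": gene, "snp": snp_r, "source": "resting"})
                rows.append({"gene": gene, "snp": snp_s, "source": "stimulated"})
        elif in_r:
            rows.append({"gene": gene, "snp": er.loc[gene, "top_snp"],
                         "source": "resting"})
        else:
            rows.append({"gene": gene, "snp": es.loc[gene, "top_snp"],
                         "source": "stimulated"})
    return pd.DataFrame(rows, columns=["gene", "snp", "source"])


def reqtl_fdr(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """BH over empirical p-values; adds q and significance flags, and the
    reGene indicator (gene with >= 1 significant test)."""
    out = results.copy()
    if out.empty:
        out["q"] = []
        out["significant"] = []
        out["regene"] = []
        return out
    reject, q = bh_fdr(out["p_emp"].to_numpy(), alpha=alpha)
    out["q"] = q
    out["significant"] = reject
    regenes = set(out.loc[out["significant"], "gene"])
    out["regene"] = out["gene"].isin(regenes)
    return out


def run_reqtl(study: ExpressionStudy, panel: GenotypePanel, cell_type: str,
              egenes_by_condition: dict[str, pd.DataFrame],
              expression_override: dict[str, pd.DataFrame] | None = None,
              n_perm: int = 1000, seed: int = 0, alpha: float = 0.05,
              r2_thresh: float = 0.8,
              early_stop_s: int | None = 50) -> pd.DataFrame:
    """Full reQTL pass for one cell type.

    ``egenes_by_condition`` maps the cell type's resting and stimulated
    condition labels to their eGene tables; ``expression_override`` lets
    the caller supply the analysis-scale (e.g. INT) expression matrices.
    """
    sheets = study.samples[study.samples["cell_type"] == cell_type]
    conds = list(dict.fromkeys(sheets["condition"]))
    resting = [c for c in conds
               if (sheets.loc[sheets["condition"] == c, "treatment"]
                   == "resting").all()]
    stim = [c for c in conds if c not in resting]
    if len(resting) != 1 or len(stim) != 1:
        raise ValueError(f"cell type {cell_type} needs one resting and one "
                         "stimulated condition")
    tests = select_reqtl_tests(egenes_by_condition[resting[0]],
                               egenes_by_condition[stim[0]], panel,
                               r2_thresh=r2_thresh)
    if expression_override:
        study = ExpressionStudy(
            expression={**study.expression, **expression_override},
            genes=study.genes, samples=study.samples,
            covariate_columns=study.covariate_columns)
    rows = []
    for i, row in tests.iterrows():
        design = build_design(study, panel, row["gene"], row["snp"], cell_type)
        res = permute_condition_within_individual(
            design, n_perm=n_perm, seed=seed + i, early_stop_s=early_stop_s)
        rows.append({"gene": row["gene"], "snp": row["snp"],
                     "source": row["source"], **res})
    results = pd.DataFrame(rows)
    return reqtl_fdr(results, alpha=alpha)
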