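"""Cross-platform survival risk stratification.

Expression profiles measured on heterogeneous platforms are made comparable by
per-patient quartile categorization: each gene's value becomes -1 if below the
patient's own first quartile, +1 if above the third, 0 otherwise. A lasso-
penalized Cox proportional-hazards model is trained on the categorized matrix,
with the penalty chosen by seeded 10-fold cross-validation minimizing the
cross-validated partial-likelihood deviance. The training-median split of the
linear predictor defines high/low risk groups, transferred unchanged (same
coefficients, same cutoff) to a test cohort, where groups are compared by
log-rank test and the hazard ratio of a Cox fit on the group indicator.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv


@dataclass
class CategorizedMatrix:
    """Patients x genes values in {-1, 0, 1} plus the quartile basis used."""

    values: pd.DataFrame
    universe: str  # 'all_genes' or 'signature_genes'

    def __post_init__(self) -> None:
        if not self.values.isin([-1, 0, 1]).all().all():
            raise ValueError("categorized values must be in {-1, 0, 1}")


@dataclass
class RiskModel:
    genes: list[str]
    coefficients: np.ndarray
    penalty: float
    penalty_selection: str
    cutoff: float | None  # training median of the linear predictor
    degenerate: bool = False
    cv_deviance: dict = field(default_factory=dict)

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        missing = [g for g in self.genes if g not in X.columns]
        if missing:
            raise ValueError(f"test data missing model gene(s): {missing}")
        return X[self.genes].to_numpy(dtype=float) @ self.coefficients

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "genes": self.genes,
                    "coefficients": self.coefficients.tolist(),
                    "penalty": self.penalty,
                    "penalty_selection": self.penalty_selection,
                    "cutoff": self.cutoff,
                    "degenerate": self.degenerate,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskModel":
        d = json.loads(Path(path).read_text())
        return cls(
            genes=d["genes"],
            coefficients=np.asarray(d["coefficients"], dtype=float),
            penalty=d["penalty"],
            penalty_selection=d["penalty_selection"],
            cutoff=d["cutoff"],
            degenerate=d["degenerate"],
        )


@dataclass
class SurvivalEval:
    logrank_statistic: float
    logrank_p: float
    hazard_ratio: float | None
    hr_ci: tuple[float, float] | None
    km_curves: dict[str, pd.DataFrame]
    n_events: int


def quartile_categorize(
    expr: pd.DataFrame,
    universe: list[str] | None = None,
) -> CategorizedMatrix:
    """Categorize each patient's expression by that patient's own quartiles.

    -1 if strictly below the patient's Q1 over the universe genes, +1 if
    strictly above Q3, 0 otherwise (boundary values -> 0). Quartiles use
    linear interpolation. Default universe: all measured genes.
    """
    cols = list(expr.columns) if universe is None else [g for g in universe if g in expr.columns]
    if len(cols) < 4:
        raise ValueError("need >= 4 genes in the quartile universe")
    basis = expr[cols].to_numpy(dtype=float)
    q1 = np.quantile(basis, 0.25, axis=1, method="linear")
    q3 = np.quantile(basis, 0.75, axis=1, method="linear")
    if np.any(q1 == q3):
        warnings.warn("constant patient profile(s): all categories set to 0")
    X = expr.to_numpy(dtype=float)
    out = np.zeros_like(X, dtype=int)
    out[X < q1[:, None]] = -1
    out[X > q3[:, None]] = 1
    return CategorizedMatrix(
        pd.DataFrame(out, index=expr.index, columns=expr.columns),
        universe="all_genes" if universe is None else "signature_genes",
    )


def cox_partial_loglik(time: np.ndarray, event: np.ndarray, lp: np.ndarray) -> float:
    """Cox partial log-likelihood with Breslow handling of tied event times."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    lp = np.asarray(lp, dtype=float)
    order = np.argsort(-time, kind="stable")  # decreasing time: risk set grows
    t_s, e_s, lp_s = time[order], event[order], lp[order]
    log_cum = np.logaddexp.accumulate(lp_s)  # log sum exp over risk set
    ll = 0.0
    i = 0
    n = len(t_s)
    while i < n:
        j = i
        while j + 1 < n and t_s[j + 1] == t_s[i]:
            j += 1
        d = e_s[i : j + 1].sum()
        if d:
            ll += lp_s[i : j + 1][e_s[i : j + 1] == 1].sum() - d * log_cum[j]
        i = j + 1
    return float(ll)


def fit_risk_model(
    X: CategorizedMatrix | pd.DataFrame,
    survival: pd.DataFrame,
    n_folds: int = 10,
    seed: int = 0,
    l1_ratio: float = 1.0,
) -> RiskModel:
    """Lasso-penalized Cox fit with the penalty chosen by seeded k-fold CV.

    CV folds are stratified by event status; the CV error is the Verweij-
    van Houwelingen cross-validated partial-likelihood deviance. The cutoff is
    the training median of the linear predictor; if the selected penalty
    shrinks every coefficient to zero the model is flagged degenerate and the
    cutoff is undefined.
    """
    Xdf = X.values if isinstance(X, CategorizedMatrix) else X
    Xdf = Xdf.loc[survival.index]
    time = survival["time"].to_numpy(dtype=float)
    event = survival["event"].to_numpy(dtype=int)
    if event.sum() < 2:
        raise ValueError("need >= 2 events to fit a risk model")
    if n_folds > len(Xdf):
        raise ValueError("n_folds exceeds number of patients")
    Xa = Xdf.to_numpy(dtype=float)
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    path = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, n_alphas=50, alpha_min_ratio=0.01)
    path.fit(Xa, y)
    alphas = np.asarray(path.alphas_)

    full_ll = {}  # alpha index -> loglik of fold-model on full data
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    cv_dev = np.zeros(len(alphas))
    for train_idx, _ in skf.split(Xa, event):
        fold = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alphas=alphas, fit_baseline_model=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fold.fit(Xa[train_idx], y[train_idx])
        coefs = fold.coef_  # genes x n_alphas (alphas as requested)
        for a_i in range(len(alphas)):
            beta = coefs[:, a_i] if a_i < coefs.shape[1] else coefs[:, -1]
            lp_all = Xa @ beta
            ll_full = cox_partial_loglik(time, event, lp_all)
            ll_train = cox_partial_loglik(
                time[train_idx], event[train_idx], lp_all[train_idx]
            )
            cv_dev[a_i] += -2.0 * (ll_full - ll_train)
    best = int(np.argmin(cv_dev))
    best_alpha = float(alphas[best])

    final = CoxnetSurvivalAnalysis(
        l1_ratio=l1_ratio, alphas=[best_alpha], fit_baseline_model=False
    )
    final.fit(Xa, y)
    beta = final.coef_[:, 0]
    degenerate = bool(np.all(beta == 0))
    lp = Xa @ beta
    cutoff = None if degenerate else float(np.median(lp))
    if degenerate:
        warnings.warn("all coefficients zero at selected penalty; model degenerate")
    return RiskModel(
        genes=list(Xdf.columns),
        coefficients=beta,
        penalty=best_alpha,
        penalty_selection=f"{n_folds}-fold CV partial-likelihood deviance (seed={seed})",
        cutoff=cutoff,
        degenerate=degenerate,
        cv_deviance={"alphas": alphas.tolist(), "deviance": cv_dev.tolist()},
    )


def apply_risk_model(model: RiskModel, X_test: CategorizedMatrix | pd.DataFrame) -> pd.Series:
    """Risk groups on a test cohort: 'high' iff linear predictor > cutoff.

    Ties at the cutoff go to 'low' (strict >). Genes absent from the test data
    raise; there is no silent imputation.
    """
    if model.cutoff is None:
        raise ValueError("degenerate model has no cutoff; cannot assign groups")
    Xdf = X_test.values if isinstance(X_test, CategorizedMatrix) else X_test
    lp = model.linear_predictor(Xdf)
    return pd.Series(np.where(lp > model.cutoff, "high", "low"), index=Xdf.index)


def evaluate_groups(groups: pd.Series, survival: pd.DataFrame) -> SurvivalEval:
    """Log-rank test, hazard ratio (high vs low) with Wald 95% CI, KM curves."""
    surv = survival.loc[groups.index]
    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy(dtype=int)
    g = groups.to_numpy()
    labels = sorted(set(g))
    if len(labels) != 2 or any((g == lab).sum() == 0 for lab in labels):
        raise ValueError("need exactly two non-empty groups")
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("no events observed; refusing log-rank and hazard ratio")

    hi = g == "high"
    lr = logrank_test(time[hi], time[~hi], event[hi], event[~hi])

    df = pd.DataFrame({"time": time, "event": event, "high": hi.astype(int)})
    hr = hr_ci = None
    try:
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        hr = float(np.exp(cph.params_["high"]))
        lo, up = cph.confidence_intervals_.loc["high"]
        hr_ci = (float(np.exp(lo)), float(np.exp(up)))
    except Exception as exc:  # e.g. complete separation / no events in a group
        warnings.warn(f"hazard-ratio fit failed: {exc}")

    km = {}
    for lab in labels:
        mask = g == lab
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask], label=str(lab))
        km[str(lab)] = kmf.survival_function_.reset_index().rename(
            columns={"timeline": "time", str(lab): "survival"}
        )
    return SurvivalEval(
        logrank_statistic=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        hazard_ratio=hr,
        hr_ci=hr_ci,
        km_curves=km,
        n_events=n_events,
    )
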