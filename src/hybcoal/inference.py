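"""Scenario classification and semi-automatic ABC on simulated gene-tree profiles.

Two inference procedures consume the discordance statistics:

* **Multinomial scenario classification.**  Profiles are simulated under a
  small set of labelled scenarios; a multinomial logistic model with all ten
  main effects and the 45 two-way interactions is fit on one batch, backward
  stepwise elimination by AIC prunes interaction terms (main effects are
  protected), and the model is cross-validated on an independently seeded
  batch, summarized as a confusion matrix.

* **Semi-automatic ABC.**  Pilot simulations drawn over the prior are used to
  regress each parameter of interest (log coalescence rate; number of hybrid
  speciations) on the 11 base statistics with all pairwise interactions
  (67 coefficients).  The fitted predictions serve as summary statistics:
  a fresh simulation is accepted when its two predictions fall within an
  ellipse of a given radius (axes in units of each fit's residual SD) around
  the observed data's predictions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .coalescent import simulate_gene_trees
from .network import simulate_conditioned_network
from .params import ContributionDistribution, EpochSchedule, HaltingConfig, RateSet
from .stats import BASE_STATISTIC_NAMES, CLASSIFIER_STATISTIC_NAMES, base_statistics

__all__ = [
    "ScenarioSpec",
    "simulate_profile_statistics",
    "simulate_scenario_set",
    "example1_scenarios",
    "example2_scenarios",
    "ClassifierModel",
    "fit_multinomial_stepwise",
    "cross_validate_confusion",
    "classification_experiment",
    "simulate_coalescent_hybrid_pilot",
    "SummaryStatisticFit",
    "fit_summary_statistics",
    "ABCResult",
    "abc_rejection",
]

#: Distance-independent reticulation success: step function with a threshold
#: far beyond twice any tree depth arising in the experiments.
ALWAYS = 1e12


@dataclass(frozen=True)
class ScenarioSpec:
    """Simulator configuration for one labelled scenario."""

    label: str
    n_taxa: int
    n_loci: int
    coalescence_rate: float
    lambda_S: float = 1.0
    lambda_H: float = 0.0
    lambda_I: float = 0.0
    success_kind: str = "step"
    success_T: float = ALWAYS
    hybrid_gamma: float = 0.5
    introgression_gamma: float = 0.5
    min_reticulations: int = 0
    reduce_to_reticulations: float = math.inf

    def schedule(self) -> EpochSchedule:
        rates = RateSet(
            lambda_S=self.lambda_S,
            lambda_H=self.lambda_H,
            lambda_I=self.lambda_I,
            lambda_C=self.coalescence_rate,
            T=self.success_T,
        )
        return EpochSchedule.constant(rates, self.success_kind)

    def halting(self) -> HaltingConfig:
        return HaltingConfig(
            max_species=self.n_taxa,
            min_reticulations=self.min_reticulations,
            reduce_to_reticulations=self.reduce_to_reticulations,
        )


def simulate_profile_statistics(
    spec: ScenarioSpec, rng: np.random.Generator, include_si2: bool = False
) -> dict[str, float]:
    """One simulated network -> gene-tree profile -> base-statistics row."""
    net = simulate_conditioned_network(
        spec.schedule(),
        spec.halting(),
        rng,
        hybrid_contributions=ContributionDistribution.point(spec.hybrid_gamma),
        introgression_contributions=ContributionDistribution.point(spec.introgression_gamma),
    )
    profile = simulate_gene_trees(net, spec.n_loci, spec.coalescence_rate, rng)
    return base_statistics(profile, include_si2=include_si2)


def simulate_scenario_set(
    specs: Sequence[ScenarioSpec],
    n_replicates: int,
    rng: np.random.Generator,
    include_si2: bool = False,
) -> pd.DataFrame:
    """Feature table: one labelled base-statistics row per replicate per scenario."""
    rows = []
    for spec in specs:
        for _ in range(n_replicates):
            row = simulate_profile_statistics(spec, rng, include_si2=include_si2)
            row["label"] = spec.label
            rows.append(row)
    return pd.DataFrame(rows)


def example1_scenarios(n_taxa: int = 10, n_loci: int = 50) -> list[ScenarioSpec]:
    """Four easy scenarios: 0 or 2 hybrid speciations x slow/fast coalescence.

    The hybrid count is enforced exactly (min = reduce) with
    distance-independent success; the proposal rate 0.2*lambda_S is then
    immaterial to the count.  Contributions are 50:50; no introgression.
    """
    out = []
    for n_hyb in (0, 2):
        for coal in (5.0, 15.0):
            out.append(
                ScenarioSpec(
                    label=f"H{n_hyb},C{coal:g}",
                    n_taxa=n_taxa,
                    n_loci=n_loci,
                    coalescence_rate=coal,
                    lambda_H=0.2 if n_hyb else 0.0,
                    min_reticulations=n_hyb,
                    reduce_to_reticulations=n_hyb,
                )
            )
    return out


def example2_scenarios(n_loci: int = 150, n_taxa: int = 20) -> list[ScenarioSpec]:
    """Four harder scenarios trading reticulation against lineage sorting.

    Hybridization and introgression proposal rates rise together (0, 0.1,
    0.26, 0.4) while the coalescence rate rises (6, 10, 30, 1000), chosen so
    the unique-splits statistic varies little between scenarios.  Success is
    linear with threshold T = 1.3; contributions are 75:25 (hybrids) and
    90:10 retained:replaced (introgression).  n_loci = 10 gives the
    low-information variant of the same design.
    """
    out = []
    for rate, coal in ((0.0, 6.0), (0.1, 10.0), (0.26, 30.0), (0.4, 1000.0)):
        out.append(
            ScenarioSpec(
                label=f"C{coal:g}",
                n_taxa=n_taxa,
                n_loci=n_loci,
                coalescence_rate=coal,
                lambda_H=rate,
                lambda_I=rate,
                success_kind="linear",
                success_T=1.3,
                hybrid_gamma=0.75,
                introgression_gamma=0.1,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Feature expansion (shared by the classifier and the ABC regressions)


class FeatureExpander:
    """Z-scored main effects plus z-scored products of z-scored mains.

    Standardization moments come from the training table; interaction columns
    are indexed by pairs (i, j), i < j, into the feature-name list.
    """

    def __init__(self, feature_names: Sequence[str]):
        self.feature_names = list(feature_names)
        self.pairs = list(combinations(range(len(self.feature_names)), 2))

    def fit(self, df: pd.DataFrame) -> "FeatureExpander":
        X = df[self.feature_names].to_numpy(float)
        self.mu_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0)
        self.sd_[self.sd_ == 0] = 1.0
        Z = (X - self.mu_) / self.sd_
        P = np.column_stack([Z[:, i] * Z[:, j] for i, j in self.pairs])
        self.pmu_ = P.mean(axis=0)
        self.psd_ = P.std(axis=0)
        self.psd_[self.psd_ == 0] = 1.0
        return self

    def transform(self, df: pd.DataFrame, terms: Optional[Sequence[int]] = None) -> np.ndarray:
        """Design matrix of mains + the selected interaction columns."""
        X = df[self.feature_names].to_numpy(float)
        Z = (X - self.mu_) / self.sd_
        if terms is None:
            terms = range(len(self.pairs))
        cols = [Z]
        for t in terms:
            i, j = self.pairs[t]
            cols.append(((Z[:, i] * Z[:, j] - self.pmu_[t]) / self.psd_[t])[:, None])
        return np.hstack(cols)

    def term_name(self, t: int) -> str:
        i, j = self.pairs[t]
        return f"{self.feature_names[i]}:{self.feature_names[j]}"


# ---------------------------------------------------------------------------
# Multinomial classification


class MultinomialLogit:
    """Maximum-likelihood multinomial logistic regression by Newton's method.

    Reference-class parameterization: K-1 coefficient rows (intercept first),
    the last class pinned at zero, so the effective parameter count is
    (p + 1) * (K - 1).  A small L2 ridge keeps the optimum finite under
    complete separation; the reported log-likelihood is unpenalized.
    Supports warm starts, which makes backward stepwise selection cheap.
    """

    def __init__(self, ridge: float = 1e-3, max_iter: int = 60, tol: float = 1e-9):
        self.ridge = ridge
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X: np.ndarray, y: np.ndarray, n_classes: int,
            warm: Optional[np.ndarray] = None) -> "MultinomialLogit":
        n, p = X.shape
        K = n_classes
        Xb = np.hstack([np.ones((n, 1)), X])
        d = p + 1
        Y = np.zeros((n, K - 1))
        for k in range(K - 1):
            Y[y == k, k] = 1.0
        B = np.zeros((K - 1, d)) if warm is None else warm.copy()

        def penalized_ll(Bm):
            eta = Xb @ Bm.T
            zmax = np.maximum(eta.max(axis=1), 0.0)
            lse = zmax + np.log(np.exp(-zmax) + np.exp(eta - zmax[:, None]).sum(axis=1))
            ll = float(np.sum(np.take_along_axis(
                np.hstack([eta, np.zeros((n, 1))]), y[:, None], axis=1)) - lse.sum())
            return ll - 0.5 * self.ridge * float((Bm[:, 1:] ** 2).sum())

        ll = penalized_ll(B)
        for _ in range(self.max_iter):
            eta = Xb @ B.T
            zmax = np.maximum(eta.max(axis=1), 0.0)
            E = np.exp(eta - zmax[:, None])
            denom = np.exp(-zmax) + E.sum(axis=1)
            Q = E / denom[:, None]  # (n, K-1) class probabilities
            G = (Q - Y).T @ Xb      # gradient of -ll
            G[:, 1:] += self.ridge * B[:, 1:]
            H = np.zeros(((K - 1) * d, (K - 1) * d))
            for k in range(K - 1):
                for l in range(k, K - 1):
                    w = Q[:, k] * ((1.0 if k == l else 0.0) - Q[:, l])
                    blk = Xb.T @ (Xb * w[:, None])
                    H[k * d:(k + 1) * d, l * d:(l + 1) * d] = blk
                    if l != k:
                        H[l * d:(l + 1) * d, k * d:(k + 1) * d] = blk
            H[np.arange((K - 1) * d), np.arange((K - 1) * d)] += self.ridge
            try:
                step = np.linalg.solve(H, G.ravel()).reshape(K - 1, d)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, G.ravel(), rcond=None)[0].reshape(K - 1, d)
            # step halving on the penalized objective
            scale = 1.0
            for _half in range(30):
                Bn = B - scale * step
                ll_new = penalized_ll(Bn)
                if ll_new >= ll - 1e-12:
                    break
                scale *= 0.5
            if ll_new < ll:
                break
            converged = ll_new - ll < self.tol * (1.0 + abs(ll))
            B, ll = Bn, ll_new
            if converged:
                break
        self.coef_ = B
        eta = Xb @ B.T
        zmax = np.maximum(eta.max(axis=1), 0.0)
        lse = zmax + np.log(np.exp(-zmax) + np.exp(eta - zmax[:, None]).sum(axis=1))
        self.loglik_ = float(np.sum(np.take_along_axis(
            np.hstack([eta, np.zeros((n, 1))]), y[:, None], axis=1)) - lse.sum())
        self.n_params_ = (K - 1) * d
        self.aic_ = 2.0 * self.n_params_ - 2.0 * self.loglik_
        return self

    def predict_logits(self, X: np.ndarray) -> np.ndarray:
        Xb = np.hstack([np.ones((len(X), 1)), X])
        eta = Xb @ self.coef_.T
        return np.hstack([eta, np.zeros((len(X), 1))])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_logits(X), axis=1)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = self.predict_logits(X)
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


@dataclass
class ClassifierModel:
    expander: FeatureExpander
    terms: list[int]           # retained interaction-column indices
    clf: MultinomialLogit
    aic: float
    classes: list[str]

    @property
    def retained_interactions(self) -> list[str]:
        return [self.expander.term_name(t) for t in self.terms]

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        """Predicted class labels."""
        idx = self.clf.predict(self.expander.transform(df, self.terms))
        return np.asarray(self.classes, dtype=object)[idx]


def _drop_warm(B: np.ndarray, col: int) -> np.ndarray:
    """Warm-start coefficients for a model with design column ``col`` removed
    (column index excludes the intercept)."""
    return np.delete(B, col + 1, axis=1)


def fit_multinomial_stepwise(
    train: pd.DataFrame,
    feature_names: Sequence[str] = CLASSIFIER_STATISTIC_NAMES,
    label_col: str = "label",
    stepwise: bool = True,
    ridge: float = 1e-3,
) -> ClassifierModel:
    """Multinomial logistic fit with backward stepwise AIC over interactions.

    The model starts from all main effects plus all two-way interactions;
    backward elimination repeatedly drops the interaction whose removal most
    improves (lowers) the AIC, stopping when no removal improves it.  Main
    effects are always retained.  A weak L2 ridge keeps the fit defined under
    separation; the AIC uses the unpenalized log-likelihood with
    (p + 1) * (K - 1) parameters.
    """
    expander = FeatureExpander(feature_names).fit(train)
    classes = sorted(train[label_col].unique())
    y = np.searchsorted(np.array(classes), train[label_col].to_numpy())
    K = len(classes)
    if K < 2:
        raise ValueError("need at least two classes")

    n_main = len(expander.feature_names)
    terms = list(range(len(expander.pairs)))
    clf = MultinomialLogit(ridge=ridge).fit(expander.transform(train, terms), y, K)
    aic = clf.aic_

    if stepwise:
        improved = True
        while improved and terms:
            improved = False
            best = None
            for idx in range(len(terms)):
                cand = terms[:idx] + terms[idx + 1:]
                warm = _drop_warm(clf.coef_, n_main + idx)
                m = MultinomialLogit(ridge=ridge).fit(expander.transform(train, cand), y, K, warm=warm)
                if m.aic_ < aic - 1e-9 and (best is None or m.aic_ < best[1]):
                    best = (idx, m.aic_, m)
            if best is not None:
                idx, aic, clf = best
                terms = terms[:idx] + terms[idx + 1:]
                improved = True

    return ClassifierModel(expander=expander, terms=terms, clf=clf, aic=aic, classes=classes)


def cross_validate_confusion(model: ClassifierModel, test: pd.DataFrame, label_col: str = "label") -> pd.DataFrame:
    """K x K confusion matrix (rows = truth, columns = prediction) on held-out data."""
    pred = model.predict(test)
    classes = model.classes
    mat = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(test[label_col], pred):
        mat.loc[t, p] += 1
    return mat


def classification_experiment(
    specs: Sequence[ScenarioSpec],
    n_replicates: int,
    rng_train: np.random.Generator,
    rng_test: np.random.Generator,
    stepwise: bool = True,
) -> dict:
    """Simulate train and test batches, fit, cross-validate.

    Returns the model, the confusion matrix, and the count/fraction of fully
    correct test classifications.
    """
    train = simulate_scenario_set(specs, n_replicates, rng_train)
    test = simulate_scenario_set(specs, n_replicates, rng_test)
    model = fit_multinomial_stepwise(train, stepwise=stepwise)
    confusion = cross_validate_confusion(model, test)
    n_correct = int(np.trace(confusion.to_numpy()))
    n_total = int(confusion.to_numpy().sum())
    return {
        "model": model,
        "train": train,
        "test": test,
        "confusion": confusion,
        "n_correct": n_correct,
        "n_total": n_total,
        "accuracy": n_correct / n_total,
    }


# ---------------------------------------------------------------------------
# Semi-automatic ABC (pilot regressions + ellipse rejection)


def simulate_coalescent_hybrid_pilot(
    n_sims: int,
    rng: np.random.Generator,
    n_taxa: int = 8,
    n_loci: int = 106,
    coal_range: tuple[float, float] = (2.0, 200.0),
    max_hybrids: int = 3,
) -> pd.DataFrame:
    """Pilot/ABC simulations over the prior: log-uniform coalescence rate and
    a uniform integer number of hybrid speciations (enforced exactly, 50:50
    contributions, no introgression).  Returns the 11 base statistics plus
    the drawn ``log_coal_rate`` (natural log) and ``n_hybrids``."""
    lo, hi = math.log(coal_range[0]), math.log(coal_range[1])
    rows = []
    for _ in range(n_sims):
        n_hyb = int(rng.integers(max_hybrids + 1))
        log_coal = lo + (hi - lo) * rng.random()
        spec = ScenarioSpec(
            label=f"h{n_hyb}",
            n_taxa=n_taxa,
            n_loci=n_loci,
            coalescence_rate=math.exp(log_coal),
            lambda_H=0.2 if n_hyb else 0.0,
            min_reticulations=n_hyb,
            reduce_to_reticulations=n_hyb,
        )
        row = simulate_profile_statistics(spec, rng, include_si2=True)
        row["log_coal_rate"] = log_coal
        row["n_hybrids"] = n_hyb
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SummaryStatisticFit:
    """Linear regression of one parameter on the base statistics.

    The design has an intercept, all main effects and all pairwise
    interactions (67 coefficients for 11 statistics).  The prediction is the
    semi-automatic ABC summary statistic for that parameter.
    """

    expander: FeatureExpander
    coef: np.ndarray
    residual_sd: float
    residuals: np.ndarray = field(repr=False)
    target: str = ""

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        X = self.expander.transform(df)
        return X @ self.coef[1:] + self.coef[0]


def fit_summary_statistics(
    pilot: pd.DataFrame,
    target: str,
    feature_names: Sequence[str] = BASE_STATISTIC_NAMES,
) -> SummaryStatisticFit:
    """Least-squares fit of ``target`` on mains + pairwise interactions.

    Rank-deficient designs are handled by the minimum-norm solution.
    Reports the standard deviation of the residuals.
    """
    expander = FeatureExpander(feature_names).fit(pilot)
    X = np.hstack([np.ones((len(pilot), 1)), expander.transform(pilot)])
    y = pilot[target].to_numpy(float)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sd = float(np.std(resid))
    if sd <= 0:
        raise ValueError("degenerate fit: residual SD is zero")
    return SummaryStatisticFit(expander=expander, coef=coef, residual_sd=sd, residuals=resid, target=target)


@dataclass
class ABCResult:
    accepted: pd.DataFrame
    radius: float
    n_candidates: int

    @property
    def n_accepted(self) -> int:
        return len(self.accepted)

    def hybrid_posterior_counts(self) -> pd.Series:
        return self.accepted["n_hybrids"].value_counts().sort_index()

    def log_coal_interval(self, level: float = 0.95) -> tuple[float, float]:
        q = (1 - level) / 2
        vals = self.accepted["log_coal_rate"]
        return float(vals.quantile(q)), float(vals.quantile(1 - q))


def abc_rejection(
    sims: pd.DataFrame,
    fit_log_coal: SummaryStatisticFit,
    fit_hybrids: SummaryStatisticFit,
    observed: pd.DataFrame | pd.Series | dict,
    radius: float = 0.2,
) -> ABCResult:
    """Accept simulations whose two summary statistics fall within an ellipse
    of ``radius`` (axes scaled by each fit's residual SD) around the observed
    data's summary statistics.

    ``sims`` must be disjoint from the pilot set used to train the fits.
    """
    if isinstance(observed, dict):
        observed = pd.Series(observed)
    if isinstance(observed, pd.Series):
        observed = observed.to_frame().T
    s1 = fit_log_coal.predict(sims)
    s2 = fit_hybrids.predict(sims)
    o1 = float(fit_log_coal.predict(observed)[0])
    o2 = float(fit_hybrids.predict(observed)[0])
    d = np.sqrt(
        ((s1 - o1) / fit_log_coal.residual_sd) ** 2 + ((s2 - o2) / fit_hybrids.residual_sd) ** 2
    )
    accepted = sims[d <= radius]
    if len(accepted) == 0:
        warnings.warn(
            f"no simulations accepted at radius {radius}; increase the radius or the candidate pool"
        )
    return ABCResult(accepted=accepted.copy(), radius=radius, n_candidates=len(sims))
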