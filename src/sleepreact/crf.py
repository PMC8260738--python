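"""Linear-chain conditional random field over brain states.

The classifier models a label sequence y (one of S brain states per scan)
given the ROI feature sequence x through the Gibbs distribution

    p(y | x) = exp(<theta, phi(x, y)>) / Z(x),

where phi stacks transition indicator features t_{i,j}(y_{t-1}, y_t) with
weights lambda (S x S) and per-state linear observation features with
weights mu (S x (N+1): one weight per ROI plus a bias). Training maximizes
the l2-penalized conditional log-likelihood with a quasi-Newton iteration;
inference uses forward-backward (per-scan posterior marginals, the
continuous 0-1 "likelihood" of each state) and Viterbi (the single best
path). When the transition features are held constant and uniform
(lambda = 0, the configuration used for sleep decoding, where the waking
block structure carries no meaning) the chain factorizes and the posterior
marginal at each scan reduces to a softmax over the state scores.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

from .design import EXCLUDED, STATES, LabelSeries

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Optimizer ran out of iterations; carries the last iterate as .model."""

    def __init__(self, msg: str, model: "CRFModel"):
        super().__init__(msg)
        self.model = model


@dataclass
class FeatureMatrix:
    """Standardized T x N observation matrix with the stats used to scale it."""

    values: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    @property
    def stats(self) -> tuple[np.ndarray, np.ndarray]:
        return self.mean, self.sd


def featurize(values: np.ndarray, stats: tuple[np.ndarray, np.ndarray] | None = None) -> FeatureMatrix:
    """Per-ROI z-scoring. Pass train-set ``stats`` to scale held-out data.

    Zero-variance ROIs are mapped to all-zero columns (with a warning): a
    constant channel carries no state information and would otherwise blow
    up the scaling.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("feature matrix contains non-finite values")
    if stats is None:
        mean = values.mean(axis=0)
        sd = values.std(axis=0)
    else:
        mean, sd = (np.asarray(a, dtype=float) for a in stats)
    zero = sd <= 0
    if np.any(zero) and stats is None:
        warnings.warn(f"{int(zero.sum())} zero-variance ROI column(s) set to 0")
    safe_sd = np.where(zero, 1.0, sd)
    z = (values - mean) / safe_sd
    z[:, zero] = 0.0
    return FeatureMatrix(values=z, mean=mean, sd=sd)


@dataclass
class CRFModel:
    states: list[str]
    lam: np.ndarray                 # S x S transition weights
    mu: np.ndarray                  # S x (N+1) state weights (last col = bias)
    transitions_uniform: bool = True
    l2: float = 1e-3
    feature_mean: np.ndarray | None = None
    feature_sd: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_features(self) -> int:
        return self.mu.shape[1] - 1

    def state_scores(self, feats: FeatureMatrix) -> np.ndarray:
        """T x S matrix of mu_s . [x_t, 1]."""
        return feats.values @ self.mu[:, :-1].T + self.mu[:, -1]

    def to_json(self) -> str:
        return json.dumps(
            {
                "states": self.states,
                "lambda": self.lam.tolist(),
                "mu": self.mu.tolist(),
                "transitions_uniform": self.transitions_uniform,
                "l2": self.l2,
                "feature_mean": None if self.feature_mean is None else self.feature_mean.tolist(),
                "feature_sd": None if self.feature_sd is None else self.feature_sd.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CRFModel":
        d = json.loads(text)
        return cls(
            states=list(d["states"]),
            lam=np.asarray(d["lambda"], dtype=float),
            mu=np.asarray(d["mu"], dtype=float),
            transitions_uniform=bool(d["transitions_uniform"]),
            l2=float(d["l2"]),
            feature_mean=None if d["feature_mean"] is None else np.asarray(d["feature_mean"]),
            feature_sd=None if d["feature_sd"] is None else np.asarray(d["feature_sd"]),
        )


@dataclass
class StateLikelihoods:
    """T x S row-stochastic matrix of per-scan state posteriors."""

    probs: np.ndarray
    states: list[str]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)

    def column(self, state: str) -> np.ndarray:
        return self.probs[:, self.states.index(state)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.probs, columns=self.states)


@dataclass
class ConfusionMatrix:
    """True x predicted scan counts over the model's states."""

    counts: np.ndarray
    states: list[str]

    @property
    def per_state_accuracy(self) -> dict[str, float]:
        row = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore"):
            rec = np.where(row > 0, np.diag(self.counts) / np.where(row > 0, row, 1), np.nan)
        return dict(zip(self.states, rec))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=self.states, columns=self.states)


def _label_indices(model: CRFModel, labels: LabelSeries | np.ndarray) -> np.ndarray:
    arr = labels.labels if isinstance(labels, LabelSeries) else np.asarray(labels, dtype=object)
    if EXCLUDED in arr:
        raise ValueError("Excluded labels must be filtered out before scoring")
    try:
        return np.array([model.states.index(l) for l in arr])
    except ValueError as e:
        raise ValueError(f"label not among model states {model.states}: {e}") from e


def sequence_score(model: CRFModel, feats: FeatureMatrix, labels) -> float:
    """<theta, phi(x, y)>: transition weights along y plus state scores."""
    y = _label_indices(model, labels)
    scores = model.state_scores(feats)
    s = float(scores[np.arange(len(y)), y].sum())
    if len(y) > 1:
        s += float(model.lam[y[:-1], y[1:]].sum())
    return s


def _uniform_lam(model: CRFModel) -> bool:
    return model.transitions_uniform or np.ptp(model.lam) == 0


def log_partition(model: CRFModel, feats: FeatureMatrix) -> float:
    """log Z(x) by the forward recursion in log space."""
    scores = model.state_scores(feats)
    T = scores.shape[0]
    if _uniform_lam(model):
        c = float(model.lam.flat[0]) if model.lam.size else 0.0
        return float(logsumexp(scores, axis=1).sum() + (T - 1) * c)
    alpha = scores[0].copy()
    for t in range(1, T):
        alpha = logsumexp(alpha[:, None] + model.lam, axis=0) + scores[t]
    return float(logsumexp(alpha))


def _forward_backward(model: CRFModel, scores: np.ndarray):
    """Return (log-alpha, log-beta, logZ) for a T x S score matrix."""
    T, S = scores.shape
    lam = model.lam
    la = np.empty((T, S))
    lb = np.empty((T, S))
    la[0] = scores[0]
    for t in range(1, T):
        la[t] = logsumexp(la[t - 1][:, None] + lam, axis=0) + scores[t]
    lb[-1] = 0.0
    for t in range(T - 2, -1, -1):
        lb[t] = logsumexp(lam + scores[t + 1] + lb[t + 1], axis=1)
    return la, lb, float(logsumexp(la[-1]))


def posterior_marginals(model: CRFModel, feats: FeatureMatrix) -> StateLikelihoods:
    """p(y_t = s | x) for every scan t, via forward-backward.

    With uniform transitions this is the per-scan softmax of the state
    scores; rows are renormalized so each sums to one exactly.
    """
    scores = model.state_scores(feats)
    if _uniform_lam(model):
        probs = softmax(scores, axis=1)
    else:
        la, lb, logz = _forward_backward(model, scores)
        probs = np.exp(la + lb - logz)
    probs /= probs.sum(axis=1, keepdims=True)
    return StateLikelihoods(probs=probs, states=list(model.states))


def pairwise_marginals(model: CRFModel, feats: FeatureMatrix) -> np.ndarray:
    """(T-1) x S x S matrix of p(y_{t-1}=i, y_t=j | x)."""
    scores = model.state_scores(feats)
    T, S = scores.shape
    if T < 2:
        return np.zeros((0, S, S))
    if _uniform_lam(model):
        m = softmax(scores, axis=1)
        return m[:-1, :, None] * m[1:, None, :]
    la, lb, logz = _forward_backward(model, scores)
    out = np.exp(
        la[:-1, :, None] + model.lam[None, :, :] + (scores[1:] + lb[1:])[:, None, :] - logz
    )
    return out / out.sum(axis=(1, 2), keepdims=True)


def viterbi_decode(model: CRFModel, feats: FeatureMatrix) -> LabelSeries:
    """argmax_y p(y | x) by max-product DP; ties go to the lower state index."""
    scores = model.state_scores(feats)
    T, S = scores.shape
    if _uniform_lam(model):
        path = np.argmax(scores, axis=1)
    else:
        delta = scores[0].copy()
        back = np.zeros((T, S), dtype=int)
        for t in range(1, T):
            cand = delta[:, None] + model.lam
            back[t] = np.argmax(cand, axis=0)
            delta = cand[back[t], np.arange(S)] + scores[t]
        path = np.empty(T, dtype=int)
        path[-1] = int(np.argmax(delta))
        for t in range(T - 1, 0, -1):
            path[t - 1] = back[t, path[t]]
    labels = np.array([model.states[i] for i in path], dtype=object)
    return LabelSeries(labels=labels, tr=np.nan)


def _empirical_counts(model: CRFModel, feats: FeatureMatrix, y: np.ndarray):
    S, N1 = model.mu.shape
    X1 = np.hstack([feats.values, np.ones((len(y), 1))])
    emp_mu = np.zeros((S, N1))
    np.add.at(emp_mu, y, X1)
    emp_lam = np.zeros((S, S))
    if len(y) > 1:
        np.add.at(emp_lam, (y[:-1], y[1:]), 1.0)
    return emp_lam, emp_mu


def log_likelihood(model: CRFModel, dataset: list[tuple[FeatureMatrix, LabelSeries]]):
    """Eq.-style penalized conditional log-likelihood and its gradient.

    Returns ``(L, (grad_lam, grad_mu))`` where
    L = sum_k [<theta, phi(x_k, y_k)> - log Z(x_k)] - l2 ||theta||^2 / 2 and
    the gradient is empirical minus expected feature counts minus l2*theta.
    When ``transitions_uniform``, lambda is a constant of the model and its
    gradient is reported as zero.
    """
    S, N1 = model.mu.shape
    L = 0.0
    g_lam = np.zeros((S, S))
    g_mu = np.zeros((S, N1))
    for feats, labels in dataset:
        y = _label_indices(model, labels)
        L += sequence_score(model, feats, y_arr(labels)) - log_partition(model, feats)
        emp_lam, emp_mu = _empirical_counts(model, feats, y)
        marg = posterior_marginals(model, feats).probs
        X1 = np.hstack([feats.values, np.ones((len(y), 1))])
        exp_mu = marg.T @ X1
        g_mu += emp_mu - exp_mu
        if not model.transitions_uniform:
            exp_lam = pairwise_marginals(model, feats).sum(axis=0)
            g_lam += emp_lam - exp_lam
    L -= model.l2 * (np.sum(model.mu**2) + (0.0 if model.transitions_uniform else np.sum(model.lam**2))) / 2
    g_mu -= model.l2 * model.mu
    if not model.transitions_uniform:
        g_lam -= model.l2 * model.lam
    return L, (g_lam, g_mu)


def y_arr(labels) -> np.ndarray:
    return labels.labels if isinstance(labels, LabelSeries) else np.asarray(labels, dtype=object)


def fit_crf(
    dataset: list[tuple[FeatureMatrix, LabelSeries]],
    states: list[str] | None = None,
    transitions_uniform: bool = True,
    l2: float = 1e-3,
    max_iter: int = 500,
    grad_tol: float = 1e-5,
    seed: int = 0,
) -> CRFModel:
    """Fit the CRF by L-BFGS on the mean per-scan penalized NLL.

    All training states must appear in the labels. With
    ``transitions_uniform`` (the default, and the configuration applied to
    sleep) lambda is pinned at 0 and only mu is estimated. Raises
    :class:`ConvergenceError` carrying the last iterate if the gradient
    max-norm has not fallen below ``grad_tol`` within ``max_iter``
    iterations.
    """
    states = list(STATES) if states is None else list(states)
    seen = set()
    for _, labels in dataset:
        seen.update(y_arr(labels).tolist())
    missing = [s for s in states if s not in seen]
    if missing:
        raise ValueError(f"training data missing state(s): {missing}")

    S = len(states)
    N = dataset[0][0].values.shape[1]
    M = sum(len(y_arr(l)) for _, l in dataset)
    rng = np.random.default_rng(seed)
    x0_mu = rng.normal(scale=1e-3, size=(S, N + 1))
    x0 = x0_mu.ravel() if transitions_uniform else np.concatenate([np.zeros(S * S), x0_mu.ravel()])

    def unpack(x):
        if transitions_uniform:
            return np.zeros((S, S)), x.reshape(S, N + 1)
        return x[: S * S].reshape(S, S), x[S * S :].reshape(S, N + 1)

    if transitions_uniform:
        # lambda pinned at 0: the chain factorizes over scans, so the NLL
        # and gradient can be computed on the pooled scan matrix in one shot
        X1 = np.vstack(
            [np.hstack([f.values, np.ones((len(y_arr(l)), 1))]) for f, l in dataset]
        )
        y_all = np.concatenate(
            [np.array([states.index(s) for s in y_arr(l)]) for _, l in dataset]
        )
        onehot = np.zeros((M, S))
        onehot[np.arange(M), y_all] = 1.0

        def objective(x):
            mu = x.reshape(S, N + 1)
            scores = X1 @ mu.T
            lse = logsumexp(scores, axis=1)
            L = scores[np.arange(M), y_all].sum() - lse.sum() - l2 * np.sum(mu**2) / 2
            probs = np.exp(scores - lse[:, None])
            g = (onehot - probs).T @ X1 - l2 * mu
            return -L / M, -g.ravel() / M

    else:

        def objective(x):
            lam, mu = unpack(x)
            m = CRFModel(states, lam, mu, transitions_uniform, l2)
            L, (g_lam, g_mu) = log_likelihood(m, dataset)
            g = np.concatenate([g_lam.ravel(), g_mu.ravel()])
            return -L / M, -g / M

    res = minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": grad_tol, "ftol": 1e-14, "maxfun": 100 * max_iter},
    )
    lam, mu = unpack(res.x)
    model = CRFModel(
        states=states,
        lam=lam,
        mu=mu,
        transitions_uniform=transitions_uniform,
        l2=l2,
        diagnostics={"n_iter": int(res.nit), "grad_max": float(np.max(np.abs(res.jac))), "fun": float(res.fun)},
    )
    grad_max = float(np.max(np.abs(res.jac)))
    if grad_max > 100 * grad_tol:
        raise ConvergenceError(
            f"CRF fit did not converge: grad max-norm {grad_max:.2e} after {res.nit} iterations",
            model,
        )
    if grad_max > grad_tol:
        logger.info("CRF fit stopped with grad max-norm %.2e (tol %.0e)", grad_max, grad_tol)
    return model


def pooled_stats(list_of_values: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Per-ROI mean/sd over the concatenation of several raw ROI matrices."""
    cat = np.vstack(list_of_values)
    return cat.mean(axis=0), cat.std(axis=0)


def cross_validate(
    subject_data: list[tuple[np.ndarray, LabelSeries]],
    states: list[str] | None = None,
    transitions_uniform: bool = True,
    l2: float = 1e-3,
    max_iter: int = 500,
    seed: int = 0,
):
    """Leave-one-subject-out cross-validation on raw (unstandardized) data.

    Each fold z-scores with the training subjects' pooled stats, fits,
    Viterbi-decodes the held-out subject, drops its Excluded scans and
    accumulates a pooled confusion matrix.
    """
    states = list(STATES) if states is None else list(states)
    if len(subject_data) < 2:
        raise ValueError("cross-validation needs at least 2 subjects")
    S = len(states)
    counts = np.zeros((S, S), dtype=float)
    for k in range(len(subject_data)):
        train = [d for i, d in enumerate(subject_data) if i != k]
        mean, sd = pooled_stats([v for v, _ in train])
        train_set = []
        for v, lab in train:
            keep = y_arr(lab) != EXCLUDED
            train_set.append((featurize(v[keep], (mean, sd)), LabelSeries(y_arr(lab)[keep], lab.tr)))
        try:
            model = fit_crf(train_set, states, transitions_uniform, l2, max_iter, seed=seed)
        except ValueError as e:
            raise ValueError(f"fold holding out subject {k}: {e}") from e
        test_v, test_lab = subject_data[k]
        pred = viterbi_decode(model, featurize(test_v, (mean, sd)))
        keep = y_arr(test_lab) != EXCLUDED
        yt = np.array([states.index(l) for l in y_arr(test_lab)[keep]])
        yp = np.array([states.index(l) for l in y_arr(pred)[keep]])
        np.add.at(counts, (yt, yp), 1.0)
    cm = ConfusionMatrix(counts=counts, states=states)
    return cm, cm.per_state_accuracy
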