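"""Ensemble species distribution modelling (presence / pseudo-absence).

The model relates presence cells on the analysis lattice to the
environmental layers of an :class:`~cwrgap.rasters.EnvStack` and projects
habitat suitability to current and future climates.  The ensemble follows
the consensus methodology common to presence-only niche modelling:

1. draw several pseudo-absence sets uniformly from valid background
   cells;
2. for each set, fit every member algorithm — a rectilinear climate
   envelope (suitability = fraction of layers whose value falls between
   the q-th and (100-q)-th percentile of the presence values) and a
   logistic regression on standardized layers;
3. evaluate each member by repeated random holdout splits with the true
   skill statistic (TSS = sensitivity + specificity - 1, maximized over
   candidate thresholds) and the rank-based AUC;
4. admit members with TSS at or above a skill cutoff and combine them
   with TSS-proportional weights: consensus suitability is the weighted
   mean, and the binary range map is a weighted majority vote of the
   members' own threshold maps.

Use :class:`EnsembleSDM` (the model) and its :meth:`~EnsembleSDM.fit`,
which returns :class:`EnsembleSDMResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .grid import CellSet
from .rasters import EnvStack

__all__ = [
    "PresenceAbsenceSet",
    "EnvelopeModel",
    "LogisticModel",
    "FittedModel",
    "EnsembleConfig",
    "EnsembleSDM",
    "EnsembleSDMResults",
    "sample_pseudo_absences",
    "fit_envelope",
    "fit_logistic",
    "evaluate",
    "best_threshold",
    "ensemble_project",
]

_SEPARATION_CAP = 8.0  # |coef| bound (standardized scale) marking separation


@dataclass(frozen=True)
class PresenceAbsenceSet:
    presences: frozenset
    absence_sets: tuple
    seed: int


def sample_pseudo_absences(
    presences: CellSet,
    env: EnvStack,
    n_sets: int = 3,
    n_per_set: int | None = None,
    seed: int = 0,
) -> PresenceAbsenceSet:
    """Draw ``n_sets`` pseudo-absence sets uniformly, without replacement,
    from valid non-presence cells.  ``n_per_set`` defaults to the
    presence count (prevalence 0.5 per set)."""
    presences = frozenset(presences)
    if n_per_set is None:
        n_per_set = len(presences)
    candidates = sorted(env.valid_cells() - presences)
    if n_per_set > len(candidates):
        raise ValueError(
            f"cannot draw {n_per_set} pseudo-absences from "
            f"{len(candidates)} candidate cells"
        )
    rng = np.random.default_rng(seed)
    sets = []
    for _ in range(n_sets):
        idx = rng.choice(len(candidates), size=n_per_set, replace=False)
        sets.append(frozenset(candidates[i] for i in idx))
    return PresenceAbsenceSet(presences=presences, absence_sets=tuple(sets), seed=seed)


# -- member algorithms ------------------------------------------------------


@dataclass(frozen=True)
class EnvelopeModel:
    """Rectilinear (percentile-trimmed) climate envelope."""

    lower: tuple  # per-layer lower bounds
    upper: tuple
    q: float

    def suitability(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        lo = np.asarray(self.lower)
        hi = np.asarray(self.upper)
        inside = (X >= lo) & (X <= hi)
        return inside.mean(axis=1)


def fit_envelope(presence_values: np.ndarray, q: float = 2.5) -> EnvelopeModel:
    """Envelope bounds at the q-th and (100-q)-th percentile per layer.

    ``presence_values`` is an (n_presences, n_layers) matrix.  q = 0
    gives the exact min/max support envelope.
    """
    X = np.atleast_2d(np.asarray(presence_values, dtype=float))
    if X.shape[0] < 1:
        raise ValueError("envelope fit needs at least one presence")
    if not (0 <= q < 50):
        raise ValueError("q must be in [0, 50)")
    lower = np.percentile(X, q, axis=0)
    upper = np.percentile(X, 100 - q, axis=0)
    return EnvelopeModel(lower=tuple(lower), upper=tuple(upper), q=q)


@dataclass(frozen=True)
class LogisticModel:
    """Logistic regression on standardized layers."""

    mean: tuple
    std: tuple
    coef: tuple  # weights for kept layers (std > 0)
    intercept: float
    kept: tuple  # indices of non-constant layers
    separation_flagged: bool = False

    def suitability(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        if self.kept:
            Z = (X[:, list(self.kept)] - np.asarray(self.mean)) / np.asarray(self.std)
            score = Z @ np.asarray(self.coef) + self.intercept
        else:
            score = np.full(X.shape[0], self.intercept)
        return 1.0 / (1.0 + np.exp(-score))


def fit_logistic(X: np.ndarray, y: np.ndarray) -> LogisticModel:
    """Maximum-likelihood logistic fit; constant layers are dropped with a
    warning and complete separation is bounded by refitting with a ridge
    penalty (flagged on the returned model)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present")
    std = X.std(axis=0)
    kept = tuple(int(i) for i in np.nonzero(std > 1e-12)[0])
    dropped = [i for i in range(X.shape[1]) if i not in kept]
    if dropped:
        warnings.warn(f"constant predictor layer(s) {dropped} dropped from logistic fit")
    if not kept:
        prevalence = float(y.mean())
        intercept = float(np.log(prevalence / (1 - prevalence))) if 0 < prevalence < 1 else 0.0
        return LogisticModel(mean=(), std=(), coef=(), intercept=intercept, kept=())
    mean = X[:, list(kept)].mean(axis=0)
    sd = X[:, list(kept)].std(axis=0)
    Z = (X[:, list(kept)] - mean) / sd
    fit = LogisticRegression(C=np.inf, max_iter=2000).fit(Z, y)
    coef = fit.coef_[0]
    separation = bool(np.max(np.abs(coef)) > _SEPARATION_CAP)
    if separation:
        fit = LogisticRegression(C=1.0, max_iter=2000).fit(Z, y)
        coef = fit.coef_[0]
    return LogisticModel(
        mean=tuple(mean),
        std=tuple(sd),
        coef=tuple(coef),
        intercept=float(fit.intercept_[0]),
        kept=kept,
        separation_flagged=separation,
    )


# -- evaluation -------------------------------------------------------------


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.empty(0)
    return np.unique(np.concatenate([[0.0], mids, [1.0]]))


def best_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(TSS, threshold) maximizing TSS; ties resolve to the lower threshold.

    A cell is predicted present when its score is >= the threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = labels == 1
    n_pos = pos.sum()
    n_neg = (~pos).sum()
    best_tss, best_th = -np.inf, 0.0
    for th in _candidate_thresholds(scores):
        pred = scores >= th
        sens = (pred & pos).sum() / n_pos
        spec = (~pred & ~pos).sum() / n_neg
        tss = sens + spec - 1.0
        if tss > best_tss:
            best_tss, best_th = tss, th
    return float(best_tss), float(best_th)


def evaluate(
    scores,
    labels,
    split: float = 0.3,
    reps: int = 5,
    seed: int = 0,
    max_retries: int = 50,
) -> tuple[float, float, float]:
    """(TSS, AUC, threshold) by repeated random holdout evaluation.

    Each rep holds out a ``split`` fraction of the scored items (both
    classes must be present; single-class draws are resampled, with an
    error after bounded retries), maximizes TSS over candidate thresholds
    on the held-out part, and computes the rank-based AUC there.  The
    returned threshold is the mean of the per-rep maximizers.  With
    ``split=0`` or ``reps=0`` the full data is evaluated once.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present")
    if split <= 0 or reps <= 0:
        tss, th = best_threshold(scores, labels)
        return tss, float(roc_auc_score(labels, scores)), th
    rng = np.random.default_rng(seed)
    n = len(scores)
    n_test = max(2, int(round(split * n)))
    tss_list, auc_list, th_list = [], [], []
    for _ in range(reps):
        for _retry in range(max_retries):
            idx = rng.choice(n, size=n_test, replace=False)
            if len(set(labels[idx].tolist())) == 2:
                break
        else:
            raise ValueError("could not draw a holdout split containing both classes")
        tss, th = best_threshold(scores[idx], labels[idx])
        tss_list.append(tss)
        th_list.append(th)
        auc_list.append(roc_auc_score(labels[idx], scores[idx]))
    return (
        float(np.mean(tss_list)),
        float(np.mean(auc_list)),
        float(np.mean(th_list)),
    )


# -- ensemble ---------------------------------------------------------------


@dataclass(frozen=True)
class FittedModel:
    """One ensemble member with its skill scores and binarization threshold."""

    kind: str  # "envelope" | "logistic"
    model: object
    tss: float
    auc: float
    threshold: float
    pa_set: int  # index of the pseudo-absence set it was trained against

    def suitability_grid(self, env: EnvStack) -> np.ndarray:
        """Suitability over the stack's valid cells (NaN where masked)."""
        out = np.full(env.grid.shape, np.nan)
        rows, cols = np.nonzero(env.mask)
        X = env.data[:, rows, cols].T
        out[rows, cols] = self.model.suitability(X)
        return out


def ensemble_project(
    members: list[FittedModel], env: EnvStack, tss_cutoff: float = 0.7
) -> tuple[np.ndarray, CellSet]:
    """TSS-weighted consensus suitability grid and binary cell set.

    Members below the skill cutoff are dropped; if none survive, the
    error names the best member score.  The binary map applies each
    member's own threshold and takes a weighted majority (>= 0.5 of the
    admitted weight).
    """
    admitted = [m for m in members if m.tss >= tss_cutoff]
    if not admitted:
        best = max((m.tss for m in members), default=float("nan"))
        raise ValueError(
            f"no ensemble member reaches TSS cutoff {tss_cutoff} (best: {best:.3f})"
        )
    raw = np.array([max(m.tss, 0.0) for m in admitted])
    weights = raw / raw.sum() if raw.sum() > 0 else np.full(len(admitted), 1 / len(admitted))
    suit = np.zeros(env.grid.shape)
    votes = np.zeros(env.grid.shape)
    for w, member in zip(weights, admitted):
        grid = member.suitability_grid(env)
        filled = np.where(np.isnan(grid), 0.0, grid)
        suit += w * filled
        votes += w * (filled >= member.threshold)
    suit[~env.mask] = np.nan
    votes[~env.mask] = 0.0
    rows, cols = np.nonzero(votes >= 0.5)
    cells = set(zip(rows.tolist(), cols.tolist()))
    return suit, cells


@dataclass(frozen=True)
class EnsembleConfig:
    """Tunable ensemble settings (all exposed; see docs/methods.md)."""

    n_pa_sets: int = 3
    n_per_set: int | None = None  # None -> presence count
    split: float = 0.3
    reps: int = 5
    tss_cutoff: float = 0.7
    envelope_q: float = 2.5
    algorithms: tuple = ("envelope", "logistic")


class EnsembleSDM:
    """Ensemble niche model for one taxon.

    Parameters
    ----------
    presences : CellSet
        Thinned presence cells on the stack's grid.
    env : EnvStack
        Training environment (current climate).
    config : EnsembleConfig, optional
    """

    def __init__(self, presences: CellSet, env: EnvStack, config: EnsembleConfig | None = None):
        self.presences = frozenset(presences)
        if not self.presences:
            raise ValueError("at least one presence cell is required")
        env.grid.validate_cells(self.presences)
        self.env = env
        self.config = config or EnsembleConfig()

    @classmethod
    def from_occurrences(cls, records, env: EnvStack, config=None, thin: bool = True):
        """Build from cleaned occurrence records (grid-dedupe + thinning)."""
        from .occurrences import dedupe_cells, thin_cells

        cells = dedupe_cells(records, env.grid)
        if thin:
            cells = thin_cells(cells)
        return cls(cells, env, config)

    def fit(self, seed: int = 0) -> "EnsembleSDMResults":
        cfg = self.config
        pa = sample_pseudo_absences(
            self.presences, self.env, cfg.n_pa_sets, cfg.n_per_set, seed
        )
        Xp = self.env.values_at(self.presences)
        members: list[FittedModel] = []
        seeds = np.random.SeedSequence(seed).generate_state(
            cfg.n_pa_sets * len(cfg.algorithms)
        )
        k = 0
        for i, absences in enumerate(pa.absence_sets):
            Xa = self.env.values_at(absences)
            X = np.vstack([Xp, Xa])
            y = np.concatenate([np.ones(len(Xp), int), np.zeros(len(Xa), int)])
            for algo in cfg.algorithms:
                if algo == "envelope":
                    model = fit_envelope(Xp, cfg.envelope_q)
                elif algo == "logistic":
                    model = fit_logistic(X, y)
                else:
                    raise ValueError(f"unknown ensemble algorithm {algo!r}")
                scores = model.suitability(X)
                tss, auc, th = evaluate(
                    scores, y, cfg.split, cfg.reps, seed=int(seeds[k] % 2**31)
                )
                members.append(
                    FittedModel(kind=algo, model=model, tss=tss, auc=auc,
                                threshold=th, pa_set=i)
                )
                k += 1
        return EnsembleSDMResults(self, pa, members, seed)


class EnsembleSDMResults:
    """Fitted ensemble: members, skills, weights, projection, summary."""

    def __init__(self, model: EnsembleSDM, pa: PresenceAbsenceSet,
                 members: list[FittedModel], seed: int):
        self.model = model
        self.pa = pa
        self.members = members
        self.seed = seed

    @property
    def config(self) -> EnsembleConfig:
        return self.model.config

    @property
    def admitted(self) -> list[FittedModel]:
        return [m for m in self.members if m.tss >= self.config.tss_cutoff]

    @property
    def weights(self) -> np.ndarray:
        raw = np.array([max(m.tss, 0.0) for m in self.admitted])
        if raw.sum() == 0:
            return np.full(len(self.admitted), 1 / max(len(self.admitted), 1))
        return raw / raw.sum()

    def project(self, env: EnvStack | None = None) -> tuple[np.ndarray, CellSet]:
        """Consensus suitability grid and binary cell set on ``env``
        (the training stack when omitted)."""
        return ensemble_project(
            self.members, env or self.model.env, self.config.tss_cutoff
        )

    def summary(self) -> str:
        lines = [
            "Ensemble SDM results",
            "====================",
            f"presences: {len(self.model.presences)} cells   "
            f"pseudo-absence sets: {self.config.n_pa_sets}   seed: {self.seed}",
            f"TSS cutoff: {self.config.tss_cutoff}   admitted: "
            f"{len(self.admitted)}/{len(self.members)} members",
            "",
            f"{'member':<12}{'PA set':>7}{'TSS':>8}{'AUC':>8}{'thresh':>9}{'weight':>9}",
        ]
        weights = {id(m): w for m, w in zip(self.admitted, self.weights)}
        for m in self.members:
            w = weights.get(id(m))
            lines.append(
                f"{m.kind:<12}{m.pa_set:>7}{m.tss:>8.3f}{m.auc:>8.3f}"
                f"{m.threshold:>9.3f}{('%9.3f' % w) if w is not None else '        -'}"
            )
        return "\n".join(lines)

    def to_manifest(self) -> dict:
        """Machine-readable dump of members, scores and settings."""
        return {
            "seed": self.seed,
            "n_presences": len(self.model.presences),
            "config": {
                "n_pa_sets": self.config.n_pa_sets,
                "n_per_set": self.config.n_per_set,
                "split": self.config.split,
                "reps": self.config.reps,
                "tss_cutoff": self.config.tss_cutoff,
                "envelope_q": self.config.envelope_q,
                "algorithms": list(self.config.algorithms),
            },
            "members": [
                {
                    "kind": m.kind,
                    "pa_set": m.pa_set,
                    "tss": m.tss,
                    "auc": m.auc,
                    "threshold": m.threshold,
                }
                for m in self.members
            ],
        }
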