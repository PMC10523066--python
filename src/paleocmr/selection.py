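"""Candidate-set enumeration, AICc ranking and coefficient averaging.

The canonical candidate set crosses 11 survival (phi) structures — time
plus the additive/multiplicative combinations of body size, geographical
range and the mass-extinction flag — with the mirror-image 11 seniority
(gamma) structures (recovery flag in place of mass extinction) and a
single detection structure (time + size), 121 models per class.  Models
are ranked by AICc; coefficients of association from models carrying at
least a weight threshold (default 0.01) are averaged, weighted by their
renormalized AICc support, with Burnham-Anderson unconditional standard
errors.  Selectivity is reported on the log-odds-of-extinction scale:
the background coefficient is the averaged trait main effect and the
mass-extinction coefficient the averaged (main + trait.ME interaction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .fit import FitResult
from .formulas import ModelSpec, ParameterStructure

logger = logging.getLogger(__name__)

__all__ = [
    "PHI_STRUCTURES",
    "enumerate_model_set",
    "reduced_model_set",
    "ModelTable",
    "SelectivityEstimate",
    "rank_models",
    "average_coefficients",
    "regime_support_summary",
]

#: the 11 canonical survival structures (gamma mirrors them with Rec)
PHI_STRUCTURES: tuple[tuple[str, ...], ...] = (
    ("time",),
    ("time", "size"),
    ("time", "range"),
    ("time", "size", "range"),
    ("time", "size*range"),
    ("time", "size*ME"),
    ("time", "range*ME"),
    ("time", "size*ME", "range"),
    ("time", "size", "range*ME"),
    ("time", "size*ME", "range*ME"),
    ("time", "size*range*ME"),
)


def _mirror_gamma(terms: tuple[str, ...]) -> tuple[str, ...]:
    return tuple(t.replace("ME", "Rec") for t in terms)


def enumerate_model_set(include_dot_gamma: bool = False) -> list[ModelSpec]:
    """The canonical 121-model crossing (11 phi x 11 gamma x 1 p).

    ``include_dot_gamma`` appends the intercept-only origination variant
    ('~1' gamma) for each phi structure, an extension some published
    selection tables require; it is off by default so the canonical count
    stays 121.
    """
    p = ParameterStructure("p", ("time", "size"))
    gammas = [
        ParameterStructure("gamma", _mirror_gamma(t)) for t in PHI_STRUCTURES
    ]
    if include_dot_gamma:
        gammas.append(ParameterStructure("gamma", ("1",)))
    specs = [
        ModelSpec(ParameterStructure("phi", ph), g, p)
        for ph, g in product(PHI_STRUCTURES, gammas)
    ]
    ids = [s.model_id for s in specs]
    assert len(set(ids)) == len(ids)
    return specs


def reduced_model_set() -> list[ModelSpec]:
    """An 8-model subset for desk-scale regime-recovery experiments.

    Four single-regime and four two-regime survival structures crossed
    with a time-only origination structure and the standard detection
    structure; enough to let AICc distinguish one selectivity regime from
    two without fitting the full canonical set.
    """
    phis = (
        ("time",),
        ("time", "size"),
        ("time", "range"),
        ("time", "size", "range"),
        ("time", "range*ME"),
        ("time", "size", "range*ME"),
        ("time", "size*ME", "range"),
        ("time", "size*ME", "range*ME"),
    )
    g = ParameterStructure("gamma", ("time",))
    p = ParameterStructure("p", ("time", "size"))
    return [ModelSpec(ParameterStructure("phi", ph), g, p) for ph in phis]


@dataclass
class ModelTable:
    """AICc-ranked table of fitted models with Akaike weights."""

    frame: pd.DataFrame  # rank, model_id, formulas, loglik, k, AICc, dAICc, weight
    fits: dict[str, FitResult]
    ess: int

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def best(self) -> FitResult:
        return self.fits[self.frame.iloc[0]["model_id"]]


@dataclass(frozen=True)
class SelectivityEstimate:
    """Model-averaged log-odds-of-extinction coefficient for one
    class x trait x regime cell, per 1 SD of the trait."""

    class_name: str
    trait: str  # 'size' | 'range'
    regime: str  # 'background' | 'mass_extinction'
    coefficient: float
    se: float
    ci_low: float
    ci_high: float
    n_models: int


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1); +inf when n <= k+1."""
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values: np.ndarray) -> np.ndarray:
    delta = aicc_values - np.min(aicc_values)
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def rank_models(
    fits: list[FitResult],
    ess_rule: str = "histories",
    histories=None,
) -> ModelTable:
    """Rank converged fits by AICc and attach Akaike weights.

    Non-converged fits are excluded and logged.  ``ess_rule`` sets the
    AICc effective sample size: ``'histories'`` (genus count, default),
    ``'detections'`` (total detections) or ``'cells'`` (histories x
    occasions); the latter two need the ``histories`` set.
    """
    ok = [f for f in fits if f.converged]
    dropped = len(fits) - len(ok)
    if dropped:
        logger.info("rank_models: %d non-converged fits excluded", dropped)
    if not ok:
        raise ValueError("no converged fits to rank")
    if ess_rule == "histories":
        n = ok[0].n_histories
    elif ess_rule == "detections":
        if histories is None:
            raise ValueError("ess_rule='detections' needs the history set")
        n = int(histories.detections.sum())
    elif ess_rule == "cells":
        if histories is None:
            raise ValueError("ess_rule='cells' needs the history set")
        n = int(histories.detections.size)
    else:
        raise ValueError(f"unknown ess_rule {ess_rule!r}")
    rows = []
    for f in ok:
        a = aicc(f.loglik, f.k, n)
        if not np.isfinite(a):
            logger.warning(
                "%s: n - k - 1 <= 0 (n=%d, k=%d); AICc set to +inf",
                f.model_id,
                n,
                f.k,
            )
        fml = f.spec.formulas()
        rows.append(
            {
                "model_id": f.model_id,
                "extinction": fml["extinction"],
                "origination": fml["origination"],
                "sampling": fml["sampling"],
                "loglik": f.loglik,
                "k": f.k,
                "AICc": a,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["AICc", "model_id"], kind="mergesort"
    ).reset_index(drop=True)
    finite = np.isfinite(df["AICc"].to_numpy())
    w = np.zeros(len(df))
    if finite.any():
        w[finite] = akaike_weights(df.loc[finite, "AICc"].to_numpy())
    df["dAICc"] = df["AICc"] - df["AICc"].iloc[0]
    df["weight"] = w
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return ModelTable(frame=df, fits={f.model_id: f for f in ok}, ess=n)


def _regime_theta(
    fit: FitResult, trait: str, regime: str
) -> tuple[float, float]:
    """(theta, se) on the extinction scale for one trait x regime in one model.

    Background: the negated survival-scale trait main effect.  Mass
    extinction: negated (main + trait.ME interaction), with the SE from
    the coefficient covariance.  Absent terms contribute 0 with zero
    variance (full-model zero substitution).
    """
    main_i, inter_i = fit.phi_indices([trait, f"{trait}:ME"])
    idx = [i for i in ([main_i] if regime == "background" else [main_i, inter_i]) if i is not None]
    if not idx:
        return 0.0, 0.0
    theta = -float(fit.beta[idx].sum())
    sub = fit.vcov[np.ix_(idx, idx)]
    if np.all(np.isfinite(sub)):
        se = float(np.sqrt(max(float(sub.sum()), 0.0)))
    else:
        se = float("nan")
    return theta, se


def average_coefficients(
    table: ModelTable,
    min_weight: float = 0.01,
    class_name: str = "",
    renormalize: bool = True,
) -> list[SelectivityEstimate]:
    """Model-averaged selectivity per trait x regime.

    Models with weight >= ``min_weight`` (and usable SEs) contribute;
    their weights are renormalized over that subset unless
    ``renormalize=False``.  The unconditional SE follows
    sqrt(sum_i w_i (se_i^2 + (theta_i - theta_bar)^2)).
    """
    df = table.frame
    qualifying = list(df.loc[df["weight"] >= min_weight, "model_id"])
    # a qualifying model must deliver finite SEs for every trait x regime
    # cell it contributes to; confounded fits are excluded with a log entry
    cells = [
        (t, r) for t in ("size", "range") for r in ("background", "mass_extinction")
    ]
    ids = [
        m
        for m in qualifying
        if all(
            np.isfinite(_regime_theta(table.fits[m], t, r)[1]) for t, r in cells
        )
    ]
    n_excluded = len(qualifying) - len(ids)
    if n_excluded:
        logger.info(
            "average_coefficients: %d qualifying models without valid SEs "
            "excluded",
            n_excluded,
        )
    if not ids:
        raise ValueError(
            f"no model reaches weight {min_weight} with valid standard errors"
        )
    w = df.set_index("model_id").loc[ids, "weight"].to_numpy()
    if renormalize:
        w = w / w.sum()

    out = []
    for trait in ("size", "range"):
        for regime in ("background", "mass_extinction"):
            thetas, ses = zip(
                *(_regime_theta(table.fits[m], trait, regime) for m in ids)
            )
            thetas = np.array(thetas)
            ses = np.array(ses)
            theta_bar = float(np.sum(w * thetas))
            se_u = float(
                np.sqrt(np.sum(w * (ses**2 + (thetas - theta_bar) ** 2)))
            )
            out.append(
                SelectivityEstimate(
                    class_name=class_name,
                    trait=trait,
                    regime=regime,
                    coefficient=theta_bar,
                    se=se_u,
                    ci_low=theta_bar - 1.959963984540054 * se_u,
                    ci_high=theta_bar + 1.959963984540054 * se_u,
                    n_models=len(ids),
                )
            )
    return out


def selectivity_frame(estimates: list[SelectivityEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "class": [e.class_name for e in estimates],
            "trait": [e.trait for e in estimates],
            "regime": [e.regime for e in estimates],
            "coefficient": [e.coefficient for e in estimates],
            "se": [e.se for e in estimates],
            "ci_low": [e.ci_low for e in estimates],
            "ci_high": [e.ci_high for e in estimates],
        }
    )


def regime_support_summary(table: ModelTable) -> dict:
    """Summed Akaike weight of single- vs two-regime survival models.

    A model is two-regime when its phi structure contains any ME term
    (distinct selectivity at mass-extinction stages), single-regime
    otherwise.
    """
    df = table.frame
    two = np.array(
        [
            any("ME" in t for t in table.fits[m].spec.phi.terms)
            for m in df["model_id"]
        ]
    )
    w_two = float(df["weight"].to_numpy()[two].sum())
    w_one = float(df["weight"].to_numpy()[~two].sum())
    best_two = bool(two[0])
    return {
        "weight_single_regime": w_one,
        "weight_two_regime": w_two,
        "best_model_id": df.iloc[0]["model_id"],
        "best_model_class": "two-regime" if best_two else "single-regime",
    }
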