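"""Covariate structures and design matrices for the three CMR families.

Each fitted model combines one structure per parameter family:

* ``phi``   — survival across a stage boundary (its complement is the
  extinction probability);
* ``gamma`` — seniority (probability a genus present at occasion t was
  already present at t-1; the Pradel handle on origination);
* ``p``     — detection (sampling) probability.

A structure is an R-style formula shorthand over ``time`` (occasion fixed
effects), ``size`` (class-standardized log10 biovolume, constant per
genus), ``range`` (class-x-stage-standardized log10 geographical range,
time-varying) and the 0/1 regime flags ``ME`` (mass-extinction stage, phi
only) and ``Rec`` (recovery stage, gamma only).  Crossings expand R-style:
``size*ME`` contributes the size main effect plus the size.ME interaction
column (the ME main effect is absorbed by the occasion fixed effects and
is therefore never a separate column).

Linear predictors live on the logit scale; survival-scale coefficients
negate to the log-odds-of-extinction scale reported downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .occurrences import CaptureHistorySet
from .timescale import StageTable

__all__ = [
    "ParameterStructure",
    "ModelSpec",
    "FamilyDesign",
    "DesignMatrices",
    "build_design",
]

_FAMILIES = ("phi", "gamma", "p")

# interaction flag allowed per family: regime shifts act on survival (ME)
# and on seniority/origination (Rec) only
_FLAG_FOR_FAMILY = {"phi": "ME", "gamma": "Rec", "p": None}

_EXPANSIONS = {
    "1": [],
    "time": [],
    "size": ["size"],
    "range": ["range"],
    "size*range": ["size", "range", "size:range"],
    "size*ME": ["size", "size:ME"],
    "range*ME": ["range", "range:ME"],
    "size*range*ME": [
        "size",
        "range",
        "size:range",
        "size:ME",
        "range:ME",
        "size:range:ME",
    ],
    "size*Rec": ["size", "size:Rec"],
    "range*Rec": ["range", "range:Rec"],
    "size*range*Rec": [
        "size",
        "range",
        "size:range",
        "size:Rec",
        "range:Rec",
        "size:range:Rec",
    ],
}

_PAPER_NAMES = {"size": "BS", "range": "GR", "ME": "ME", "Rec": "Rec"}


@dataclass(frozen=True)
class ParameterStructure:
    """Covariate structure for one parameter family.

    ``terms`` is an ordered tuple of shorthand terms, e.g.
    ``("time", "size", "range*ME")`` or ``("1",)`` for intercept-only.
    """

    family: str
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        object.__setattr__(self, "terms", tuple(self.terms))
        flag = _FLAG_FOR_FAMILY[self.family]
        for t in self.terms:
            if t not in _EXPANSIONS:
                raise ValueError(f"unknown term {t!r} for family {self.family}")
            if "ME" in t and flag != "ME":
                raise ValueError(f"ME terms not allowed in family {self.family}")
            if "Rec" in t and flag != "Rec":
                raise ValueError(f"Rec terms not allowed in family {self.family}")
        if "1" in self.terms and len(self.terms) > 1:
            raise ValueError("'1' (intercept-only) cannot be combined")

    @property
    def has_time(self) -> bool:
        return "time" in self.terms

    def covariate_columns(self) -> list[str]:
        """Expanded covariate column names, deduplicated in order."""
        cols: list[str] = []
        for t in self.terms:
            for c in _EXPANSIONS[t]:
                if c not in cols:
                    cols.append(c)
        return cols

    def formula(self) -> str:
        """Render in the field's notation, e.g. '~time + BS + GR x ME'."""
        parts = []
        for t in self.terms:
            if t in ("time", "1"):
                parts.append(t)
            else:
                parts.append(
                    " × ".join(_PAPER_NAMES[x] for x in t.split("*"))
                )
        return "~" + " + ".join(parts)


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: a structure per family plus a stable id."""

    phi: ParameterStructure
    gamma: ParameterStructure
    p: ParameterStructure

    def __post_init__(self) -> None:
        for slot, fam in (("phi", "phi"), ("gamma", "gamma"), ("p", "p")):
            if getattr(self, slot).family != fam:
                raise ValueError(f"structure in slot {slot} has wrong family")

    @property
    def model_id(self) -> str:
        return (
            f"phi({'+'.join(self.phi.terms)})"
            f".gamma({'+'.join(self.gamma.terms)})"
            f".p({'+'.join(self.p.terms)})"
        )

    def formulas(self) -> dict[str, str]:
        return {
            "extinction": self.phi.formula(),
            "origination": self.gamma.formula(),
            "sampling": self.p.formula(),
        }


@dataclass
class FamilyDesign:
    """Design for one family over its occasion grid.

    The linear predictor for genus i at family-occasion t is
    ``eta[i, t] = alpha[time_index[t]] + sum_j cov[j][i, t] * beta[j]``
    where ``alpha`` has one entry per occasion under a ``time`` structure
    and a single intercept otherwise.  Covariate columns identically zero
    over the data (e.g. an ME interaction in a window with no flagged
    stage) are pruned before fitting and reported with estimate NaN.
    """

    family: str
    n_occasions: int
    has_time: bool
    cov_names: list[str]
    cov: np.ndarray  # (n_cov, n_genera, n_occasions)
    pruned: list[str] = field(default_factory=list)
    me: np.ndarray | None = None  # 0/1 mass-extinction flag per occasion
    rec: np.ndarray | None = None  # 0/1 recovery flag per occasion

    @property
    def n_time_cols(self) -> int:
        return self.n_occasions if self.has_time else 1

    @property
    def n_cols(self) -> int:
        return self.n_time_cols + len(self.cov_names)

    @property
    def col_names(self) -> list[str]:
        if self.has_time:
            time_cols = [f"t{j + 1}" for j in range(self.n_occasions)]
        else:
            time_cols = ["(Intercept)"]
        return time_cols + list(self.cov_names)

    def eta(self, beta: np.ndarray, n_genera: int) -> np.ndarray:
        """(n_genera, n_occasions) linear predictor."""
        a = beta[: self.n_time_cols]
        if self.has_time:
            eta = np.broadcast_to(a, (n_genera, self.n_occasions)).copy()
        else:
            eta = np.full((n_genera, self.n_occasions), a[0])
        b = beta[self.n_time_cols :]
        for j in range(len(b)):
            eta += b[j] * self.cov[j]
        return eta

    def project(self, deta: np.ndarray) -> np.ndarray:
        """Map d(loglik)/d(eta) of shape (n, T_fam) to the gradient in beta."""
        if self.has_time:
            g_time = deta.sum(axis=0)
        else:
            g_time = np.array([deta.sum()])
        g_cov = np.array([(deta * self.cov[j]).sum() for j in range(len(self.cov))])
        return np.concatenate([g_time, g_cov])


@dataclass
class DesignMatrices:
    """Per-family designs sharing one capture-history set."""

    phi: FamilyDesign
    gamma: FamilyDesign
    p: FamilyDesign
    n_genera: int

    @property
    def k(self) -> int:
        """Total retained columns across families (the AICc parameter count)."""
        return self.phi.n_cols + self.gamma.n_cols + self.p.n_cols

    def split(self, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        k1, k2 = self.phi.n_cols, self.gamma.n_cols
        return beta[:k1], beta[k1 : k1 + k2], beta[k1 + k2 :]

    @property
    def col_names(self) -> list[tuple[str, str]]:
        out = []
        for fam in ("phi", "gamma", "p"):
            out += [(fam, c) for c in getattr(self, fam).col_names]
        return out


def _base_covariate(
    name: str,
    histories: CaptureHistorySet,
    occ_stage: np.ndarray,
    me: np.ndarray,
    rec: np.ndarray,
) -> np.ndarray:
    """(n, T_fam) values of one expanded column over the family occasions."""
    n = histories.n_genera
    parts = name.split(":")
    out = np.ones((n, len(occ_stage)))
    for part in parts:
        if part == "size":
            out *= histories.z_size[:, None]
        elif part == "range":
            out *= histories.z_range[:, occ_stage]
        elif part == "ME":
            out *= me[occ_stage][None, :]
        elif part == "Rec":
            out *= rec[occ_stage][None, :]
        else:  # pragma: no cover
            raise ValueError(f"unknown covariate part {part!r}")
    return out


def build_design(
    spec: ModelSpec,
    histories: CaptureHistorySet,
    stage_table: StageTable | None = None,
    range_timing: str = "start",
) -> DesignMatrices:
    """Construct design matrices for one model over one history set.

    Occasion grids: phi has T-1 intervals (interval t spans stage t to
    t+1), gamma has T-1 occasions (occasions 2..T, indexing the occasion
    entered), p has T occasions.  For phi's interval t the time-varying
    range covariate and the ME flag are taken from stage t when
    ``range_timing='start'`` (default) or stage t+1 when ``'end'``.
    """
    table = stage_table if stage_table is not None else histories.stage_table
    T = histories.n_occasions
    if len(table) != T:
        raise ValueError("stage table length does not match history window")
    if T < 2:
        raise ValueError("need at least 2 occasions")
    if range_timing not in ("start", "end"):
        raise ValueError("range_timing must be 'start' or 'end'")
    me = np.array([float(s.is_mass_extinction) for s in table])
    rec = np.array([float(s.is_recovery) for s in table])

    shift = 0 if range_timing == "start" else 1
    occ_stage = {
        "phi": np.arange(T - 1) + shift,  # interval t -> stage t (or t+1)
        "gamma": np.arange(1, T),  # occasion entered
        "p": np.arange(T),
    }

    designs = {}
    for fam in _FAMILIES:
        structure: ParameterStructure = getattr(spec, fam)
        stages = occ_stage[fam]
        names = structure.covariate_columns()
        mats, kept, pruned = [], [], []
        for name in names:
            m = _base_covariate(name, histories, stages, me, rec)
            if np.all(m == 0.0):
                pruned.append(name)
            else:
                mats.append(m)
                kept.append(name)
        cov = (
            np.stack(mats)
            if mats
            else np.zeros((0, histories.n_genera, len(stages)))
        )
        designs[fam] = FamilyDesign(
            family=fam,
            n_occasions=len(stages),
            has_time=structure.has_time,
            cov_names=kept,
            cov=cov,
            pruned=pruned,
            me=me[stages],
            rec=rec[stages],
        )
    return DesignMatrices(
        phi=designs["phi"],
        gamma=designs["gamma"],
        p=designs["p"],
        n_genera=histories.n_genera,
    )
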