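"""Core kinetic model of TIM-2 mediated ferritin-iron handling.

The model extends a five-variable iron-homeostasis core (LIP, TfR1, Fpn,
endogenous H-ferritin, active IRPs) with a four-variable TIM-2 receptor
cycle: free membrane receptor, membrane-bound TIM-2.Fe-HFt complex,
endosomal receptor, and surviving exogenous HFt inside the cell.  All
labelled pools are expressed in pmol of 55Fe-equivalents per 10^6 cells
(specific-activity assumption: counts are proportional to tracer amount);
receptor pools are expressed in iron-binding-capacity equivalents so that
binding moves label conservatively.

Two bookkeeping pools close the tracer budget: ``media_unbound`` (label in
the culture media not yet cell-associated) and ``media_exported``
(cumulative label exported through the ferroportin route).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "InvalidParameterError",
    "StateDomainError",
    "EquilibrationError",
    "ModelParameters",
    "StateVector",
    "STATE_NAMES",
    "hill_promote",
    "hill_inhibit",
    "rhs",
    "make_rhs",
    "equilibrate",
]


class InvalidParameterError(ValueError):
    """A rate constant, threshold, or fraction violates its domain."""


class StateDomainError(ValueError):
    """A state entry is negative beyond numerical tolerance."""


class EquilibrationError(RuntimeError):
    """Equilibration failed to reach the residual tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


# ---------------------------------------------------------------------------
# Hill-type regulatory factors
# ---------------------------------------------------------------------------

def hill_promote(x: float, alpha: float, k: float) -> float:
    """Saturating promotion term ``alpha * x / (k + x)``.

    ``x`` is the level of the promoting pool, ``alpha`` the maximum rate and
    ``k`` the activation threshold (half-maximal point).  The value lies in
    ``[0, alpha]`` for non-negative ``x``.
    """
    _check_hill_args(x, alpha, k)
    return alpha * x / (k + x)


def hill_inhibit(x: float, alpha: float, k: float) -> float:
    """Suppression term ``alpha * k / (k + x)``.

    Unsuppressed (``alpha``) at ``x = 0`` and reduced to half at ``x = k``.
    """
    _check_hill_args(x, alpha, k)
    return alpha * k / (k + x)


def _check_hill_args(x: float, alpha: float, k: float) -> None:
    if k <= 0:
        raise InvalidParameterError(f"threshold must be positive, got k={k}")
    if alpha < 0:
        raise InvalidParameterError(f"maximum rate must be >= 0, got alpha={alpha}")
    if x < 0:
        raise StateDomainError(f"pool level must be >= 0, got x={x}")


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

_FRACTION_FIELDS = ("alpha9", "alpha10", "alpha11")


@dataclass
class ModelParameters:
    """Rate constants, thresholds and branching fractions of the model.

    Units: rates are per minute; thresholds are in the units of the pool
    they gate (labelled pools: pmol per 10^6 cells); ``alpha9``, ``alpha10``
    and ``alpha11`` are unitless fractions in ``[0, 1]``.

    Several kinetic products are only identifiable from these data as lumped
    single coefficients and are stored as such:

    ``alpha7_Ftex``
        TIM-2 / Fe-HFt combination rate (alpha7 * exogenous-ferritin level).
    ``alpha1_Feex_x2``
        direct (TIM-2 independent) uptake coefficient, first order on the
        unbound media label.
    ``alpha6_x3_eff``
        effective first-order LIP export coefficient through ferroportin.

    ``alpha10`` defaults to ``1 - alpha9`` (iron from processed complexes
    not retained in surviving HFt is released to the LIP) and ``alpha11``
    to 1, which makes the tracer budget close exactly.

    With ``frozen_core`` set (the default, the model's linear regime) the
    regulatory pools x2/x3/x5 are held at their label-free equilibrium and
    their Hill factors fold into effective constants; the full regulatory
    dynamics integrate when the flag is off.

    ``literal_processing`` switches the x9/LIP gain terms from the
    ferritin-suppressed processing flux (the default, which conserves
    tracer) to the unsuppressed literal form ``gamma7 * x7``.
    """

    # TIM-2 pathway (extracted controlling parameters)
    alpha7_Ftex: float = 0.166
    gamma7: float = 0.118
    gamma6: float = 0.0142
    alpha9: float = 0.283
    gamma9: float = 0.00031
    K47: float = 0.11
    alpha1_Feex_x2: float = 0.00015
    alpha6_x3_eff: float = 0.0019

    # iron released from HFt degradation routed to the LIP
    alpha10: float | None = None
    alpha11: float = 1.0

    # homeostasis core (inert under frozen_core except storage/release)
    alpha2: float = 0.01
    gamma2: float = 0.01
    alpha3: float = 0.01
    gamma3: float = 0.008
    gammah_Hep: float = 0.002
    alpha4_storage: float = 0.0008
    gamma4: float = 0.0001
    alpha5: float = 0.01
    gamma5: float = 0.01
    k15: float = 1.0
    k52: float = 1.0
    k53: float = 1.0
    k54: float = 1.0

    frozen_core: bool = True
    literal_processing: bool = False

    def __post_init__(self) -> None:
        if self.alpha10 is None:
            self.alpha10 = 1.0 - self.alpha9
        self.validate()

    def validate(self) -> None:
        for name in (
            "alpha7_Ftex", "gamma7", "gamma6", "gamma9", "alpha1_Feex_x2",
            "alpha6_x3_eff", "alpha2", "gamma2", "alpha3", "gamma3",
            "gammah_Hep", "alpha4_storage", "gamma4", "alpha5", "gamma5",
        ):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise InvalidParameterError(f"{name} must be a finite non-negative rate, got {v}")
        for name in ("K47", "k15", "k52", "k53", "k54"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise InvalidParameterError(f"{name} must be a positive threshold, got {v}")
        for name in _FRACTION_FIELDS:
            v = getattr(self, name)
            if not math.isfinite(v) or not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1], got {v}")

    # -- frozen-core reference levels ------------------------------------
    def core_equilibrium(self, x1: float = 0.0) -> tuple[float, float, float]:
        """Label-free equilibrium of the regulatory pools (x2, x3, x5).

        IRP level responds to the LIP through the k15 threshold; TfR1 and
        Fpn follow the IRP level.  With ``x1 = 0`` this is the
        pre-treatment resting point the frozen-core regime is pinned to.
        """
        x5 = hill_inhibit(x1, self.alpha5, self.k15) / self.gamma5
        x2 = hill_promote(x5, self.alpha2, self.k52) / self.gamma2
        x3 = hill_inhibit(x5, self.alpha3, self.k53) / (self.gamma3 + self.gammah_Hep)
        return x2, x3, x5

    def storage_coefficient(self, x5: float | None = None) -> float:
        """Effective first-order LIP -> endogenous-ferritin storage rate.

        The maximum rate ``alpha4_storage`` is gated by the IRP inhibition
        factor ``k54 / (k54 + x5)``; under the frozen core the factor is
        evaluated at the label-free resting IRP level.
        """
        if x5 is None:
            x5 = self.core_equilibrium()[2]
        return hill_inhibit(x5, self.alpha4_storage, self.k54)

    # -- (de)serialisation -------------------------------------------------
    def replace(self, **changes: float) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: Mapping) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise InvalidParameterError(f"unknown parameter name(s): {sorted(unknown)}")
        return cls(**dict(mapping))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# State
# ---------------------------------------------------------------------------

STATE_NAMES = (
    "x1", "x2", "x3", "x4", "x5", "x6", "x7", "x8", "x9",
    "media_unbound", "media_exported",
)
# array indices
(I_X1, I_X2, I_X3, I_X4, I_X5, I_X6, I_X7, I_X8, I_X9,
 I_MEDIA_UNBOUND, I_MEDIA_EXPORTED) = range(11)

N_STATE = 11

_STATE_TOL = 1e-6  # absolute tolerance for negative-entry checks


@dataclass
class StateVector:
    """Labelled-iron pools plus receptor and media bookkeeping.

    x1: label in the LIP; x4: label in endogenous HFt; x7: label in
    membrane TIM-2.Fe-HFt complexes; x9: label in surviving exogenous HFt.
    x2/x3/x5: TfR1, Fpn and active-IRP regulatory levels (model units).
    x6/x8: free-membrane and endosomal TIM-2 binding capacity
    (pmol Fe-equivalent per 10^6 cells).
    """

    x1: float = 0.0
    x2: float = 0.0
    x3: float = 0.0
    x4: float = 0.0
    x5: float = 0.0
    x6: float = 0.0
    x7: float = 0.0
    x8: float = 0.0
    x9: float = 0.0
    media_unbound: float = 0.0
    media_exported: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "StateVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (N_STATE,):
            raise ValueError(f"state array must have shape ({N_STATE},), got {arr.shape}")
        return cls(**dict(zip(STATE_NAMES, arr)))

    @property
    def cell_total_label(self) -> float:
        return self.x1 + self.x4 + self.x7 + self.x9

    @property
    def total_label(self) -> float:
        return self.cell_total_label + self.media_unbound + self.media_exported

    @property
    def tim2_total(self) -> float:
        return self.x6 + self.x7 + self.x8

    def validate(self, tol: float = _STATE_TOL) -> None:
        for n in STATE_NAMES:
            if getattr(self, n) < -tol:
                raise StateDomainError(f"pool {n} is negative: {getattr(self, n)}")


def _as_state_array(state) -> np.ndarray:
    if isinstance(state, StateVector):
        return state.to_array()
    arr = np.asarray(state, dtype=float)
    if arr.shape != (N_STATE,):
        raise ValueError(f"state must have {N_STATE} entries, got shape {arr.shape}")
    return arr


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------

def make_rhs(
    params: ModelParameters,
    tim2_present: bool = True,
    media_reference: float | None = None,
    ferritin_media: bool = True,
    check_state: bool = False,
):
    """Build a fast ``f(t, y) -> dy`` closure for the model ODEs.

    ``media_reference`` is the media label level at which the lumped
    binding coefficient ``alpha7_Ftex`` applies; the binding flux is scaled
    by the remaining unbound-media fraction so that label cannot be created
    when the media deplete.  ``None`` keeps the constant-external-ferritin
    form (fraction pinned at 1).  ``ferritin_media=False`` marks media label
    that is not in TIM-2 bindable Fe-HFt form (e.g. transferrin-bound
    residue in the export experiment), which zeroes the binding flux.
    """
    params.validate()
    p = params
    a7 = p.alpha7_Ftex if (tim2_present and ferritin_media) else 0.0
    g6, g7, k47 = p.gamma6, p.gamma7, p.K47
    a9, g9 = p.alpha9, p.gamma9
    a10, a11 = p.alpha10, p.alpha11
    a1 = p.alpha1_Feex_x2
    a6 = p.alpha6_x3_eff
    g4 = p.gamma4
    frozen = p.frozen_core
    literal = p.literal_processing
    tim2 = tim2_present
    mref = media_reference

    x5_frozen = p.core_equilibrium()[2]
    s4_frozen = p.storage_coefficient(x5_frozen)
    a2, g2 = p.alpha2, p.gamma2
    a3, g3h = p.alpha3, p.gamma3 + p.gammah_Hep
    a4max, k54 = p.alpha4_storage, p.k54
    a5, g5, k15, k52, k53 = p.alpha5, p.gamma5, p.k15, p.k52, p.k53

    def f(t: float, y) -> np.ndarray:
        x1, x2, x3, x4, x5, x6, x7, x8, x9, mu, me = y
        if check_state:
            for v, n in zip(y, STATE_NAMES):
                if v < -_STATE_TOL:
                    raise StateDomainError(f"pool {n} is negative: {v}")

        if mu <= 0.0:
            f_media = 0.0          # no unbound label left to bind
        elif mref is None:
            f_media = 1.0          # constant-external-ferritin form
        elif mref <= 0.0:
            f_media = 0.0
        else:
            f_media = min(mu / mref, 1.0)

        binding = a7 * x6 * f_media                     # media label -> x7
        direct = a1 * max(mu, 0.0)                      # media label -> LIP
        export = a6 * x1                                # LIP -> media
        if frozen:
            storage = s4_frozen * x1                    # LIP -> endogenous HFt
        else:
            storage = a4max * k54 / (k54 + x5) * x1
        release = g4 * x4                               # endogenous HFt -> LIP

        if tim2:
            processing = g7 * k47 / (k47 + x4 + x9) * x7    # endocytosis flux
            source = (g7 * x7) if literal else processing
        else:
            processing = 0.0
            source = 0.0

        dy = np.empty(N_STATE)
        dy[I_X1] = direct + release - export - storage + a10 * source + a11 * g9 * x9
        dy[I_X4] = storage - release
        dy[I_X9] = a9 * source - g9 * x9
        if tim2:
            dy[I_X6] = g6 * x8 - binding
            dy[I_X7] = binding - processing
            dy[I_X8] = processing - g6 * x8
        else:
            dy[I_X6] = dy[I_X7] = dy[I_X8] = 0.0
        if frozen:
            dy[I_X2] = dy[I_X3] = dy[I_X5] = 0.0
        else:
            dy[I_X2] = a2 * x5 / (k52 + x5) - g2 * x2
            dy[I_X3] = a3 * k53 / (k53 + x5) - g3h * x3
            dy[I_X5] = a5 * k15 / (k15 + x1) - g5 * x5
        dy[I_MEDIA_UNBOUND] = -binding - direct
        dy[I_MEDIA_EXPORTED] = export
        return dy

    return f


def rhs(
    state,
    params: ModelParameters,
    tim2_present: bool = True,
    media_reference: float | None = None,
    ferritin_media: bool = True,
) -> np.ndarray:
    """Time derivative of the state (per minute).

    Accepts a :class:`StateVector` or an 11-vector ordered as
    :data:`STATE_NAMES`; returns the derivative as an array in the same
    order.  Negative entries beyond tolerance raise
    :class:`StateDomainError`.
    """
    y = _as_state_array(state)
    f = make_rhs(params, tim2_present, media_reference, ferritin_media, check_state=True)
    return f(0.0, y)


# ---------------------------------------------------------------------------
# Equilibration
# ---------------------------------------------------------------------------

def equilibrate(
    params: ModelParameters,
    media_label: float = 0.0,
    cell_preload: float = 0.0,
    tim2_capacity: float = 0.0,
    tim2_present: bool = True,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> StateVector:
    """Pre-treatment resting state of the system.

    The regulatory pools sit at their equilibrium; with no label anywhere
    every labelled pool is zero and the residual of the right-hand side
    vanishes (checked against ``tol``).  A ``cell_preload`` (pmol per 10^6
    cells of cell-internal label, e.g. from transferrin loading) is
    partitioned between endogenous ferritin and the LIP according to the
    storage/release balance ``x4 / x1 = storage_coefficient / gamma4`` —
    the quasi-equilibrium of the storage exchange; the slow export drain
    means the full residual is not zero in that case, by design.
    """
    if media_label < 0 or cell_preload < 0 or tim2_capacity < 0:
        raise InvalidParameterError("media_label, cell_preload and tim2_capacity must be >= 0")
    params.validate()

    x1 = 0.0
    if params.frozen_core:
        x2, x3, x5 = params.core_equilibrium(0.0)
        s4 = params.storage_coefficient(x5)
        if cell_preload > 0:
            x1 = cell_preload * params.gamma4 / (params.gamma4 + s4)
    else:
        # x5 responds to the labelled LIP; iterate partition <-> x5
        x1 = 0.0
        x2 = x3 = x5 = 0.0
        prev = math.inf
        for _ in range(max_iter):
            x2, x3, x5 = params.core_equilibrium(x1)
            s4 = params.storage_coefficient(x5)
            x1 = cell_preload * params.gamma4 / (params.gamma4 + s4) if cell_preload > 0 else 0.0
            if abs(x1 - prev) < tol * max(1.0, cell_preload):
                break
            prev = x1
        else:
            raise EquilibrationError(
                "preload partition did not converge", residual=abs(x1 - prev)
            )
    x4 = cell_preload - x1

    state = StateVector(
        x1=x1, x2=x2, x3=x3, x4=x4, x5=x5,
        x6=tim2_capacity if tim2_present else 0.0,
        x7=0.0, x8=0.0, x9=0.0,
        media_unbound=media_label, media_exported=0.0,
    )

    if media_label == 0.0 and cell_preload == 0.0:
        residual = float(np.max(np.abs(rhs(state, params, tim2_present=tim2_present))))
        if residual > tol:
            raise EquilibrationError(
                f"label-free equilibrium residual {residual:.3e} exceeds tol {tol:.1e}",
                residual=residual,
            )
    return state
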