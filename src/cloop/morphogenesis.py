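"""Morphogenesis tensors driving cardiac c-looping.

Each developmental process (endodermal contraction, cardiac-jelly growth,
dorsal-mesocardium tension, differential myocardial growth, myocardial
cell-shape change, vein-fusion elongation, regional isotropic growth) is
prescribed as a diagonal growth tensor in the local (e_R, e_Theta, e_Z)
material frame, with its scalar parameter ramping linearly in pseudo-time
over a two-step protocol: an *initial* step that establishes the HH10-
reference state (initial jelly growth and contraction only) followed by a
*looping* step spanning HH10- to HH12 during which every process acts.

The total morphogenesis tensor of an element is the product of all active
process tensors; since all factors are diagonal in the shared local frame
the product order is immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "KINDS",
    "MorphProcess",
    "MorphSchedule",
    "baseline_schedule",
    "process_tensor",
    "ramp_value",
    "total_morphogenesis",
]

KINDS = (
    "contraction",
    "cj_growth",
    "dm_tension",
    "differential_growth",
    "cell_shape",
    "fusion",
    "isotropic_growth",
)

_GROWTH_KINDS = {"cj_growth", "differential_growth", "cell_shape", "fusion",
                 "isotropic_growth"}


def growth_gradient(theta: np.ndarray) -> np.ndarray:
    """G(theta) = 2*theta/pi + 1: longitudinal hypertrophy gradient.

    Equals the determinant of the differential-growth tensor; growth is
    smallest at the dorsal midline (theta=0, inner curvature) and largest
    ventrally (theta=pi, outer curvature).
    """
    theta = np.asarray(theta, dtype=float)
    return 2.0 * theta / np.pi + 1.0


def shape_factor(value, theta: np.ndarray) -> np.ndarray:
    """S(theta) = (value-1)*(theta/pi-1)^2 + 1: cell-shape modulation.

    Maximal circumferential elongation at the dorsal side (theta=0), none
    at the ventral midline (theta=pi); isovolumetric by construction.
    """
    theta = np.asarray(theta, dtype=float)
    return (np.asarray(value, float) - 1.0) * (theta / np.pi - 1.0) ** 2 + 1.0


@dataclass(frozen=True)
class MorphProcess:
    """One morphogenetic process with its region selector and time course.

    ``regions`` entries are selector strings resolved against named element
    masks; ``"HT:MY"`` means the intersection of the HT and MY masks.
    ``param_initial`` is the value reached at the end of the initial step
    (only meaningful for ``step="both"``); every ramp starts from 1.
    """

    kind: str
    param_final: float
    regions: tuple[str, ...]
    step: str = "looping"  # "initial" | "looping" | "both"
    param_initial: float = 1.0
    name: str = ""

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown process kind {self.kind!r}")
        if self.step not in ("initial", "looping", "both"):
            raise ValueError(f"unknown step {self.step!r}")
        for p in (self.param_initial, self.param_final):
            if not p > 0:
                raise ValueError(f"{self.kind}: parameter must be positive, got {p}")
        if self.kind == "contraction" and max(self.param_initial, self.param_final) > 1:
            raise ValueError("contraction parameter must be <= 1")
        if self.kind in _GROWTH_KINDS and min(self.param_initial, self.param_final) < 1:
            raise ValueError(f"{self.kind}: growth parameter must be >= 1")
        if not self.name:
            object.__setattr__(self, "name", self.kind)


@dataclass(frozen=True)
class MorphSchedule:
    """Process list plus the pseudo-time layout of the two-step protocol."""

    processes: tuple[MorphProcess, ...]
    step_durations: tuple[float, float] = (1.0, 1.0)

    @property
    def t_initial_end(self) -> float:
        return self.step_durations[0]

    @property
    def t_end(self) -> float:
        return self.step_durations[0] + self.step_durations[1]

    @property
    def stage_map(self) -> dict[str, float]:
        """Pseudo-times of the named stages: HH10- ends the initial step;
        HH10/HH11/HH12 are evenly spaced over the looping step."""
        t0, tl = self.step_durations
        return {
            "HH10-": t0,
            "HH10": t0 + tl / 3.0,
            "HH11": t0 + 2.0 * tl / 3.0,
            "HH12": t0 + tl,
        }

    def with_overrides(self, **final_by_name: float) -> "MorphSchedule":
        """Return a schedule with selected processes' endpoint replaced
        (value 1.0 disables a process entirely, both steps)."""
        procs = []
        for p in self.processes:
            if p.name in final_by_name:
                v = final_by_name[p.name]
                init = 1.0 if v == 1.0 else p.param_initial
                procs.append(replace(p, param_final=v, param_initial=init))
            else:
                procs.append(p)
        return replace(self, processes=tuple(procs))


def baseline_schedule() -> MorphSchedule:
    """The control-condition schedule (parameter endpoints of the model).

    Contraction strengthens from 0.9 at HH10- to 0.9*0.7 = 0.63 at HH12;
    jelly growth runs 1.1 -> 1.1*1.3 = 1.43; all looping-step growth ramps
    start from 1 at HH10-.
    """
    return MorphSchedule(processes=(
        MorphProcess("contraction", 0.63, ("SPL", "FG", "AIP"), "both", 0.9),
        MorphProcess("cj_growth", 1.43, ("HT:CJ",), "both", 1.1),
        MorphProcess("dm_tension", 0.8, ("DM",), "looping"),
        MorphProcess("differential_growth", 1.3, ("HT:MY",), "looping"),
        MorphProcess("cell_shape", 1.3, ("HT:MY",), "looping"),
        MorphProcess("fusion", 1.5, ("HT",), "looping"),
        MorphProcess("isotropic_growth", 1.3, ("CT",), "looping", name="ct_growth"),
        MorphProcess("isotropic_growth", 1.6, ("LOV_cranial",), "looping", name="lov_growth"),
        MorphProcess("isotropic_growth", 1.2, ("ROV_cranial",), "looping", name="rov_growth"),
    ))


def ramp_fraction(process: MorphProcess, t: float, schedule: MorphSchedule) -> float:
    """Fraction of the process's looping-step ramp completed at time ``t``."""
    t0, tl = schedule.step_durations
    return float(np.clip((float(t) - t0) / tl, 0.0, 1.0))


def ramp_value(process: MorphProcess, t: float, schedule: MorphSchedule) -> float:
    """Linearly ramped parameter value of ``process`` at pseudo-time ``t``."""
    t0, tl = schedule.step_durations
    t = float(t)
    if process.step == "initial":
        frac = np.clip(t / t0, 0.0, 1.0)
        return 1.0 + frac * (process.param_final - 1.0)
    if process.step == "looping":
        frac = np.clip((t - t0) / tl, 0.0, 1.0)
        return 1.0 + frac * (process.param_final - 1.0)
    # both: 1 -> param_initial over the initial step, then -> param_final
    if t <= t0:
        frac = np.clip(t / t0, 0.0, 1.0)
        return 1.0 + frac * (process.param_initial - 1.0)
    frac = np.clip((t - t0) / tl, 0.0, 1.0)
    return process.param_initial + frac * (process.param_final - process.param_initial)


def process_tensor(kind: str, value, theta=0.0) -> np.ndarray:
    """Diagonal of the process tensor in local (R, Theta, Z) order.

    ``value`` and ``theta`` broadcast; returns shape ``(..., 3)`` holding
    the diagonal entries (all process tensors are diagonal in the local
    frame).
    """
    if kind not in KINDS:
        raise ValueError(f"unknown process kind {kind!r}")
    value = np.asarray(value, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(value <= 0):
        raise ValueError(f"{kind}: value must be positive")
    if kind in ("differential_growth", "cell_shape") and (
        np.any(theta < -1e-12) or np.any(theta > np.pi + 1e-12)
    ):
        raise ValueError("theta must lie in [0, pi]")
    value, theta = np.broadcast_arrays(value, theta)
    one = np.ones_like(value)
    if kind == "contraction":
        diag = np.stack([value**-2, value, value], axis=-1)
    elif kind in ("cj_growth", "isotropic_growth"):
        diag = np.stack([value, value, value], axis=-1)
    elif kind in ("dm_tension", "fusion"):
        diag = np.stack([one, one, value], axis=-1)
    elif kind == "differential_growth":
        G = growth_gradient(theta)
        diag = np.stack([value, value, G / value**2], axis=-1)
    else:  # cell_shape
        S = shape_factor(value, theta)
        diag = np.stack([one, S, 1.0 / S], axis=-1)
    return diag


def _resolve_selector(selector: str, masks: dict[str, np.ndarray]) -> np.ndarray:
    parts = selector.split(":")
    try:
        mask = masks[parts[0]].copy()
        for p in parts[1:]:
            mask &= masks[p]
    except KeyError as e:
        raise KeyError(f"region selector {selector!r}: no mask named {e.args[0]!r}")
    return mask


def total_morphogenesis(
    t: float,
    schedule: MorphSchedule,
    masks: dict[str, np.ndarray],
    theta: np.ndarray,
    Q: np.ndarray | None = None,
) -> np.ndarray:
    """Per-element total morphogenesis tensor at pseudo-time ``t``.

    ``masks`` maps region names to boolean element masks, ``theta`` is the
    (subregion-averaged) circumferential angle per element, and ``Q`` holds
    the local frames as columns ``[e_R e_Theta e_Z]``; if ``Q`` is None the
    local diagonal entries ``(n, 3)`` are returned instead of global 3x3
    tensors.
    """
    theta = np.asarray(theta, dtype=float)
    n = theta.shape[0]
    diag = np.ones((n, 3))
    for proc in schedule.processes:
        v = ramp_value(proc, t, schedule)
        if v == 1.0:
            continue
        sel = np.zeros(n, dtype=bool)
        for s in proc.regions:
            sel |= _resolve_selector(s, masks)
        if not sel.any():
            continue
        th = theta[sel]
        if proc.kind == "differential_growth":
            # the hypertrophy gradient G builds up linearly over the looping
            # step (G=1 at HH10-); G(f*theta) = 1 + f*(G(theta)-1) realises
            # the linear ramp while keeping det M_g = G exactly
            th = th * ramp_fraction(proc, t, schedule)
        diag[sel] *= process_tensor(proc.kind, v, th)
    if Q is None:
        return diag
    return np.einsum("nik,nk,njk->nij", Q, diag, Q)
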