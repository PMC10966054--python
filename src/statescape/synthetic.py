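"""Synthetic multi-state cohort generator.

Produces labeled frames x features matrices that emulate a two-group,
two-session, three-condition design (six state blocks per subject), with

* fixed, mutually orthogonal state mean patterns,
* a global session-2 shift shared by both groups,
* a subject-specific extra displacement of the OM2/RS2 patterns in the
  active group (antisymmetric between OM2 and RS2 so that their mutual
  separation grows with the planted latent),
* AR(1) temporally autocorrelated Gaussian noise,
* psychometric scores generated from the planted latents, with the
  generative coefficients retained for recovery tests.

Everything is deterministic given ``CohortParams.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .exceptions import ParameterError

__all__ = [
    "STATES",
    "SESSION2_STATES",
    "CohortParams",
    "LabeledTimeSeries",
    "PsychometricTable",
    "generate_subject",
    "generate_cohort",
    "generate_circle_cloud",
]

#: Canonical block order: RS, FA, OM within each session, session 1 first.
STATES: tuple[str, ...] = ("RS1", "FA1", "OM1", "RS2", "FA2", "OM2")

SESSION2_STATES = frozenset({"RS2", "FA2", "OM2"})

#: Sign of the active-group latent displacement per state.  OM2 and RS2 are
#: pushed in opposite directions along the same axis so their mutual
#: separation grows with the subject latent.
_DRUG_SIGN = {"OM2": 1.0, "RS2": -1.0}

_GROUPS = ("active", "control")

# Psychometric generative coefficients (recorded in the output table).
_COEF_DEREALIZATION = 1.0          # positive_derealization per unit latent
_COEF_INSIGHT_DEREAL = 1.0         # insightfulness per unit derealization
_COEF_INSIGHT_RETREAT = 0.5        # insightfulness per unit retreat response


@dataclass(frozen=True)
class CohortParams:
    """Parameters of the synthetic cohort generator.

    Defaults are calibrated so the planted group effect on the post-session
    OM/RS separation is detectable at 18 subjects per group, not to match
    any particular recording.
    """

    n_per_group: int = 18
    n_features: int = 200
    frames_per_state: int = 100
    state_separation: float = 4.0
    retreat_shift: float = 2.0
    drug_shift_scale: float = 3.0
    noise_sd: float = 1.0
    ar_coeff: float = 0.4
    psy_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ParameterError("n_per_group must be >= 1")
        if self.n_features < 8:
            # 6 state patterns + retreat + drug axes must be orthogonal.
            raise ParameterError("n_features must be >= 8")
        if self.frames_per_state < 1:
            raise ParameterError("frames_per_state must be >= 1")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be > 0")
        if not 0.0 <= self.ar_coeff < 1.0:
            raise ParameterError("ar_coeff must lie in [0, 1)")
        if self.psy_noise_sd <= 0:
            raise ParameterError("psy_noise_sd must be > 0")
        for name in ("state_separation", "retreat_shift", "drug_shift_scale"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


@dataclass
class LabeledTimeSeries:
    """A frames x features matrix with a per-frame state label."""

    values: np.ndarray
    labels: np.ndarray
    subject_id: str
    group: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.ndim != 2:
            raise ParameterError("values must be a 2-D matrix")
        if len(self.labels) != self.values.shape[0]:
            raise ParameterError("one label per frame required")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("values must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def state_block(self, state: str) -> np.ndarray:
        """Row indices of frames carrying ``state``."""
        return np.flatnonzero(self.labels == state)


@dataclass
class PsychometricTable:
    """Per-subject psychometric scores plus the planted ground truth.

    ``frame`` has one row per subject with columns ``subject_id``, ``group``,
    ``positive_derealization``, ``insightfulness``, ``latent_shift`` and
    ``retreat_gain``; ``coefficients`` holds the generative weights so
    recovery tests can check them.
    """

    frame: pd.DataFrame
    coefficients: dict = field(default_factory=dict)


def _direction_basis(params: CohortParams) -> np.ndarray:
    """Eight orthonormal directions shared by all subjects of a cohort.

    Rows 0..5 are the state mean directions (in ``STATES`` order), row 6 the
    session-2 (retreat) axis, row 7 the active-group displacement axis.
    """
    rng = np.random.default_rng([params.seed, 0])
    raw = rng.standard_normal((params.n_features, 8))
    q, _ = np.linalg.qr(raw)
    return q.T[:8]


def _subject_rng(params: CohortParams, subject_index: int, group: str) -> np.random.Generator:
    return np.random.default_rng([params.seed, 1, int(subject_index), _GROUPS.index(group)])


def _subject_latents(
    params: CohortParams, subject_index: int, group: str
) -> tuple[float, float]:
    """(latent_shift, retreat_gain) for one subject, deterministic."""
    rng = _subject_rng(params, subject_index, group)
    if group == "active":
        latent = float(rng.gamma(4.0, 0.25))     # mean 1, sd 0.5, right-skewed
    else:
        latent = float(rng.gamma(4.0, 0.025))    # near zero
    retreat_gain = float(1.0 + 0.2 * rng.standard_normal())
    return latent, retreat_gain


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, int],
               sd: float, ar: float) -> np.ndarray:
    innovations = rng.normal(0.0, sd, size=shape)
    if ar == 0.0:
        return innovations
    # Stationary start: inflate the first innovation to the marginal sd.
    innovations[0] /= np.sqrt(1.0 - ar * ar)
    return signal.lfilter([1.0], [1.0, -ar], innovations, axis=0)


def generate_subject(
    params: CohortParams, subject_index: int, group: str
) -> LabeledTimeSeries:
    """Generate one subject's six-block labeled time series.

    Frame model per state block::

        x_t = m(state) + retreat_shift * retreat_gain * u * [session 2]
              + drug_shift * sign(state) * w * [state in {OM2, RS2}, active]
              + AR(1) noise

    where ``m``, ``u``, ``w`` are fixed orthonormal directions and
    ``drug_shift = drug_shift_scale * latent_shift`` with a per-subject
    latent.  Deterministic given ``(params.seed, subject_index, group)``.
    """
    if group not in _GROUPS:
        raise ParameterError(f"group must be one of {_GROUPS}, got {group!r}")
    if subject_index < 0:
        raise ParameterError("subject_index must be >= 0")

    basis = _direction_basis(params)
    state_dirs = {s: basis[i] for i, s in enumerate(STATES)}
    u, w = basis[6], basis[7]

    latent, retreat_gain = _subject_latents(params, subject_index, group)
    drug_shift = params.drug_shift_scale * latent

    n_frames = 6 * params.frames_per_state
    mean = np.empty((n_frames, params.n_features))
    labels = np.empty(n_frames, dtype=object)
    for i, state in enumerate(STATES):
        m = params.state_separation * state_dirs[state]
        if state in SESSION2_STATES:
            m = m + params.retreat_shift * retreat_gain * u
        if group == "active" and state in _DRUG_SIGN:
            m = m + drug_shift * _DRUG_SIGN[state] * w
        sl = slice(i * params.frames_per_state, (i + 1) * params.frames_per_state)
        mean[sl] = m
        labels[sl] = state

    noise_rng = np.random.default_rng(
        [params.seed, 3, int(subject_index), _GROUPS.index(group)]
    )
    noise = _ar1_noise(noise_rng, (n_frames, params.n_features),
                       params.noise_sd, params.ar_coeff)

    return LabeledTimeSeries(
        values=mean + noise,
        labels=labels,
        subject_id=f"sub-{subject_index:03d}",
        group=group,
    )


def generate_cohort(
    params: CohortParams,
) -> tuple[list[LabeledTimeSeries], PsychometricTable]:
    """Generate a full two-group cohort plus its psychometric table.

    Active subjects receive indices ``0 .. n_per_group-1``, control subjects
    ``n_per_group .. 2*n_per_group-1``.
    """
    subjects: list[LabeledTimeSeries] = []
    rows = []
    psy_rng = np.random.default_rng([params.seed, 2])
    for i in range(2 * params.n_per_group):
        group = "active" if i < params.n_per_group else "control"
        subjects.append(generate_subject(params, i, group))
        latent, retreat_gain = _subject_latents(params, i, group)
        derealization = (
            _COEF_DEREALIZATION * latent
            + psy_rng.normal(0.0, params.psy_noise_sd)
        )
        retreat_response = params.retreat_shift * retreat_gain
        insight = (
            _COEF_INSIGHT_DEREAL * derealization
            + _COEF_INSIGHT_RETREAT * retreat_response
            + psy_rng.normal(0.0, params.psy_noise_sd)
        )
        rows.append(
            {
                "subject_id": subjects[-1].subject_id,
                "group": group,
                "positive_derealization": derealization,
                "insightfulness": insight,
                "latent_shift": latent,
                "retreat_gain": retreat_gain,
            }
        )
    table = PsychometricTable(
        frame=pd.DataFrame(rows),
        coefficients={
            "derealization_per_latent": _COEF_DEREALIZATION,
            "insight_per_derealization": _COEF_INSIGHT_DEREAL,
            "insight_per_retreat_response": _COEF_INSIGHT_RETREAT,
            "psy_noise_sd": params.psy_noise_sd,
        },
    )
    return subjects, table


def generate_circle_cloud(
    n: int,
    radius: float,
    noise_sd: float,
    seed: int,
    *,
    equally_spaced: bool = False,
) -> np.ndarray:
    """n x 2 point cloud on a circle with Gaussian radial noise."""
    if n < 8:
        raise ParameterError("n must be >= 8")
    if radius <= 0:
        raise ParameterError("radius must be > 0")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if equally_spaced:
        theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    else:
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    r = radius + rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.full(n, radius)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])
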