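"""Synthetic calibration experiments: array geometry + stochastic RSSI.

Field calibration uses "arrays" of 12 or 18 tags mounted on crossbars (3
tags per 1.9-m pole), deployed for 15-minute trials in each habitat at
two heights, every tag pulsing once per 20 s.  This module builds such
array geometries and simulates the received pulses under the full
hierarchical error model::

    RSSI = kappa(h,z) + beta(h,z) r - 20 log10 r + gamma delta(theta,phi)
           + send(tx) + receive(rx) + exchange(pair, stratum)
           + replicate(directed pair, trial) + eps

so every downstream stage (fitting, inversion) is testable without field
data.  Per-tag (send, receive) effects are drawn from a bivariate normal
with configurable covariance; all draws are reproducible under a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .logstore import TagLog
from .propagation import (
    ALL_STRATA,
    PropagationParams,
    Stratum,
    directivity_db,
    expected_rssi,
    fold_angle,
)

__all__ = [
    "CROSSBAR_LENGTH",
    "PULSE_INTERVAL_S",
    "TRIAL_DURATION_S",
    "OBSERVATION_COLUMNS",
    "ArrayDesign",
    "GeneratorTruth",
    "build_array",
    "directed_pair_geometry",
    "simulate_calibration",
    "observations_to_taglogs",
]

CROSSBAR_LENGTH = 1.9  # m, 3 tags per bar
PULSE_INTERVAL_S = 20.0  # one pulse per tag per 20 s
TRIAL_DURATION_S = 900.0  # 15-minute trials

#: Endpoints of the calibration distance range; the default geometry is
#: tuned so the extreme pairwise distances land exactly here.
MIN_PAIR_DISTANCE = 0.93
MAX_PAIR_DISTANCE = 25.07

#: Schema of the observation table produced by simulate_calibration.
OBSERVATION_COLUMNS = (
    "sender_id",
    "receiver_id",
    "r",
    "theta",
    "phi",
    "habitat",
    "height",
    "trial_id",
    "replicate_id",
    "rssi",
)


@dataclass(frozen=True)
class ArrayDesign:
    """Geometry of one deployed tag array in one stratum.

    positions : (n, 2) tag coordinates in metres.
    bearings  : (n,) antenna "forward" bearings in degrees CCW from +x.
    tag_ids   : integer tag identities (shared identities across designs
                model the same physical tags re-deployed).
    """

    positions: np.ndarray
    bearings: np.ndarray
    tag_ids: np.ndarray
    stratum: Stratum
    trial_id: int = 0
    duration_s: float = TRIAL_DURATION_S

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array")
        n = pos.shape[0]
        if len(self.bearings) != n or len(self.tag_ids) != n:
            raise ValueError("positions, bearings and tag_ids must align")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "bearings", np.asarray(self.bearings, dtype=float))
        object.__setattr__(self, "tag_ids", np.asarray(self.tag_ids, dtype=int))

    @property
    def n_tags(self) -> int:
        return self.positions.shape[0]

    def with_stratum(self, stratum: Stratum, trial_id: int | None = None) -> "ArrayDesign":
        return replace(
            self,
            stratum=stratum,
            trial_id=self.trial_id if trial_id is None else trial_id,
        )


@dataclass(frozen=True)
class GeneratorTruth:
    """Ground-truth parameters of the synthetic calibration generator."""

    params: dict[Stratum, PropagationParams]
    var_send: float = 1.0
    var_receive: float = 1.0
    cov_send_receive: float = 0.412
    var_exchange: dict[str, float] = field(default_factory=dict)
    var_replicate: float = 1.0
    var_residual: float = 4.0

    def __post_init__(self) -> None:
        for name in ("var_send", "var_receive", "var_replicate", "var_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in self.var_exchange.values()):
            raise ValueError("exchange variances must be >= 0")
        bound = np.sqrt(self.var_send * self.var_receive)
        if abs(self.cov_send_receive) > bound + 1e-12:
            raise ValueError(
                "send/receive covariance implies |correlation| > 1: "
                f"|{self.cov_send_receive}| > {bound}"
            )

    @property
    def send_receive_cov(self) -> np.ndarray:
        return np.array(
            [
                [self.var_send, self.cov_send_receive],
                [self.cov_send_receive, self.var_receive],
            ]
        )

    def exchange_var(self, stratum: Stratum) -> float:
        return float(self.var_exchange.get(stratum.label, 0.0))

    @classmethod
    def noiseless(
        cls, params: dict[Stratum, PropagationParams]
    ) -> "GeneratorTruth":
        """All variance components zero: RSSI is deterministic."""
        return cls(
            params=params,
            var_send=0.0,
            var_receive=0.0,
            cov_send_receive=0.0,
            var_exchange={},
            var_replicate=0.0,
            var_residual=0.0,
        )


# Default crossbar y-positions.  The nearest pair of bars sits 0.93 m
# apart (the shortest calibration distance) and the farthest bar is
# placed so the longest diagonal pair spans exactly 25.07 m.
_FAR_Y = float(np.sqrt(MAX_PAIR_DISTANCE**2 - CROSSBAR_LENGTH**2))
_DEFAULT_BAR_Y_12 = (0.0, MIN_PAIR_DISTANCE, 7.5, _FAR_Y)
_DEFAULT_BAR_Y_18 = (0.0, MIN_PAIR_DISTANCE, 1.93, 7.5, 15.0, _FAR_Y)

#: Antenna bearing cycle (degrees) giving relative in-plane angles that
#: span the full 0-180 degree range, including parallel and
#: perpendicular pairs.
_BEARING_CYCLE = (90.0, 135.0, 0.0, 45.0)


def build_array(
    n_tags: int = 12,
    bar_positions: tuple[float, ...] | None = None,
    stratum: Stratum = ALL_STRATA[0],
    trial_id: int = 0,
) -> ArrayDesign:
    """Build the default row-of-crossbars array geometry.

    Tags sit in threes on horizontal crossbars (at x = -0.95, 0, +0.95 m)
    stacked along the y axis at ``bar_positions``.  With the defaults the
    minimum pairwise tag distance is exactly 0.93 m and the maximum
    exactly 25.07 m; ``n_tags`` must be divisible by 3.
    """
    if n_tags % 3 != 0 or n_tags < 3:
        raise ValueError(f"n_tags must be a positive multiple of 3, got {n_tags}")
    if bar_positions is None:
        if n_tags == 12:
            bar_positions = _DEFAULT_BAR_Y_12
        elif n_tags == 18:
            bar_positions = _DEFAULT_BAR_Y_18
        else:
            raise ValueError(
                "no default bar layout for n_tags="
                f"{n_tags}; pass bar_positions explicitly"
            )
    if 3 * len(bar_positions) != n_tags:
        raise ValueError(
            f"{len(bar_positions)} bars hold {3 * len(bar_positions)} tags, "
            f"not {n_tags}"
        )
    half = CROSSBAR_LENGTH / 2.0
    xs = np.tile([-half, 0.0, half], len(bar_positions))
    ys = np.repeat(np.asarray(bar_positions, dtype=float), 3)
    positions = np.column_stack([xs, ys])
    ids = np.arange(n_tags)
    bearings = np.array([_BEARING_CYCLE[i % len(_BEARING_CYCLE)] for i in ids])
    return ArrayDesign(
        positions=positions,
        bearings=bearings,
        tag_ids=ids,
        stratum=stratum,
        trial_id=trial_id,
    )


def directed_pair_geometry(design: ArrayDesign) -> pd.DataFrame:
    """Distance and in-plane angles for every ordered tag pair.

    theta is the angle between the line of sight and the transmitter's
    broadside axis; phi the angle between the line of sight and the
    receiver's forward bearing; both folded into [0, 180] using the
    directivity's symmetries.
    """
    n = design.n_tags
    rows = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            dx, dy = design.positions[j] - design.positions[i]
            r = float(np.hypot(dx, dy))
            los = float(np.degrees(np.arctan2(dy, dx)))
            theta = fold_angle(los - (design.bearings[i] + 90.0))
            phi = fold_angle(los - design.bearings[j])
            rows.append(
                (design.tag_ids[i], design.tag_ids[j], r, theta, phi)
            )
    return pd.DataFrame(
        rows, columns=["sender_id", "receiver_id", "r", "theta", "phi"]
    )


def _draw_tag_effects(
    tag_ids: np.ndarray, truth: GeneratorTruth, rng: np.random.Generator
) -> dict[int, tuple[float, float]]:
    cov = truth.send_receive_cov
    # Degenerate covariances (zero variances) are legitimate: use the
    # matrix square root via eigen-decomposition instead of Cholesky.
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    root = v @ np.diag(np.sqrt(w)) @ v.T
    draws = rng.standard_normal((len(tag_ids), 2)) @ root.T
    return {int(t): (float(d[0]), float(d[1])) for t, d in zip(tag_ids, draws)}


def simulate_calibration(
    designs: ArrayDesign | list[ArrayDesign],
    truth: GeneratorTruth,
    pulses_per_direction: int = 45,
    seed: int | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """Simulate calibration observations for one or more array trials.

    Every ordered tag pair in every trial yields ``pulses_per_direction``
    pulses (the default, 45, is a 15-minute trial at one pulse per 20 s).
    Tag-level (send, receive) effects are drawn once per distinct tag id
    across all trials; exchange effects once per (unordered pair,
    stratum); replicate effects once per directed pair per trial;
    residuals fresh per pulse.  Returns a DataFrame with columns
    ``OBSERVATION_COLUMNS``, bit-reproducible for a fixed seed.
    """
    if pulses_per_direction < 1:
        raise ValueError("pulses_per_direction must be >= 1")
    if isinstance(designs, ArrayDesign):
        designs = [designs]
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    all_ids = np.unique(np.concatenate([d.tag_ids for d in designs]))
    tag_effects = _draw_tag_effects(all_ids, truth, rng)

    exchange: dict[tuple[int, int, str], float] = {}
    frames = []
    for design in designs:
        stratum = design.stratum
        if stratum not in truth.params:
            raise ValueError(f"no propagation parameters for stratum {stratum.label}")
        params = truth.params[stratum]
        geom = directed_pair_geometry(design)
        sd_ex = np.sqrt(truth.exchange_var(stratum))
        sd_rep = np.sqrt(truth.var_replicate)
        sd_res = np.sqrt(truth.var_residual)

        pair_rows = []
        for row in geom.itertuples(index=False):
            tx, rx = int(row.sender_id), int(row.receiver_id)
            key = (min(tx, rx), max(tx, rx), stratum.label)
            if key not in exchange:
                exchange[key] = float(rng.normal(0.0, sd_ex)) if sd_ex > 0 else 0.0
            mean = (
                expected_rssi(row.r, params, directivity_db(row.theta, row.phi))
                + tag_effects[tx][0]
                + tag_effects[rx][1]
                + exchange[key]
            )
            rep_effect = float(rng.normal(0.0, sd_rep)) if sd_rep > 0 else 0.0
            eps = (
                rng.normal(0.0, sd_res, size=pulses_per_direction)
                if sd_res > 0
                else np.zeros(pulses_per_direction)
            )
            rssi = mean + rep_effect + eps
            replicate_id = f"t{design.trial_id}:{tx}->{rx}"
            pair_rows.append(
                pd.DataFrame(
                    {
                        "sender_id": tx,
                        "receiver_id": rx,
                        "r": row.r,
                        "theta": row.theta,
                        "phi": row.phi,
                        "habitat": stratum.habitat,
                        "height": stratum.height.value,
                        "trial_id": design.trial_id,
                        "replicate_id": replicate_id,
                        "rssi": rssi,
                    }
                )
            )
        frames.append(pd.concat(pair_rows, ignore_index=True))
    out = pd.concat(frames, ignore_index=True)
    return out[list(OBSERVATION_COLUMNS)]


def observations_to_taglogs(
    observations: pd.DataFrame,
    start_tick: int = 0,
    round_rssi: bool = True,
) -> list[TagLog]:
    """Re-express simulated observations as single-pulse encounter logs.

    Pulses for each directed pair are timestamped on the 20-s pulse grid
    starting at ``start_tick``.  By default RSSI is rounded to integer dB,
    matching the hardware's quantised output; pass ``round_rssi=False``
    to keep the continuous values.
    """
    logs = []
    tick_step = int(PULSE_INTERVAL_S * 64)
    counters: dict[tuple[int, int], int] = {}
    for row in observations.itertuples(index=False):
        pair = (int(row.sender_id), int(row.receiver_id))
        k = counters.get(pair, 0)
        counters[pair] = k + 1
        t = start_tick + k * tick_step
        value = round(float(row.rssi)) if round_rssi else float(row.rssi)
        logs.append(
            TagLog(
                this_id=int(row.receiver_id),
                enc_id=int(row.sender_id),
                first_time=t,
                last_time=t,
                rssi_max=value,
                rssi_min=value,
                rssi_mean=value,
                type_code=1,
            )
        )
    return logs
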