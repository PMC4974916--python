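"""Population-scale forward simulation of wild-tag pulses.

To turn a fitted calibration into distance estimates, the calibration is
pushed forward through a simulated wild population: individuals are
placed under a spatial scenario, each pulse is assigned a habitat-height
context from an observed time-budget table and uniformly random antenna
angles, and an RSSI value is drawn from the calibration model with all
its variance components.  The resulting (distance, RSSI) cloud is what
:mod:`proxcal.inversion` interrogates.

Three spatial scenarios are supported, from least to most realistic for
group-living animals:

``uniform-distance``
    inter-tag distance i.i.d. uniform on (0, max_uniform_distance];
    indifference to spatial structure.
``random-2d``
    individuals scattered uniformly in a square study area; pulse
    distances are pairwise distances of fresh uniform points.
``clustered-groups``
    individuals clustered in small groups (uniform group centres, members
    uniform in a disc), pooling within- and between-group pair distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .propagation import Height, PropagationParams, Stratum, directivity_db, expected_rssi

__all__ = [
    "SCENARIO_KINDS",
    "SpatialScenario",
    "PULSE_COLUMNS",
    "normalize_habitat_table",
    "sample_distances",
    "sample_context",
    "simulate_pulses",
]

SCENARIO_KINDS = ("uniform-distance", "random-2d", "clustered-groups")

#: Schema of the simulated wild-pulse table.
PULSE_COLUMNS = ("r", "habitat", "height", "theta", "phi", "rssi")


@dataclass(frozen=True)
class SpatialScenario:
    """Spatial layout assumptions for the simulated population.

    Defaults describe the studied crow population: 36 individuals in a
    4000 x 4000 m study area, clustering in family groups of 3 with an
    average group diameter of 10 m.  ``max_uniform_distance`` (used only
    by the uniform-distance kind) defaults to 25.07 m, the upper end of
    the calibration range — the inverted quantiles depend on this
    support, so change it deliberately.
    """

    kind: str = "clustered-groups"
    n_individuals: int = 36
    area_side: float = 4000.0
    group_size: int = 3
    group_diameter: float = 10.0
    max_uniform_distance: float = 25.07

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}; "
                             f"expected one of {SCENARIO_KINDS}")
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        if self.kind == "clustered-groups":
            if self.group_size < 1 or self.n_individuals % self.group_size:
                raise ValueError(
                    "n_individuals must be divisible by group_size for "
                    "clustered-groups"
                )
            if self.group_diameter <= 0:
                raise ValueError("group_diameter must be > 0")
        if self.kind == "uniform-distance" and self.max_uniform_distance <= 0:
            raise ValueError("max_uniform_distance must be > 0")
        if self.area_side <= 0:
            raise ValueError("area_side must be > 0")

    @property
    def n_groups(self) -> int:
        return self.n_individuals // self.group_size


def normalize_habitat_table(table: pd.DataFrame) -> pd.DataFrame:
    """Normalise a habitat-preference table to probabilities.

    Input columns: habitat, height, percent (or weight).  Percentages
    need not sum to exactly 100 (the published table sums to 100.1);
    they are rescaled to sum to 1.  All-zero tables are rejected.
    """
    col = "percent" if "percent" in table.columns else "weight"
    out = table.copy()
    weights = out[col].to_numpy(dtype=float)
    if (weights < 0).any():
        raise ValueError("habitat weights must be >= 0")
    total = weights.sum()
    if total <= 0:
        raise ValueError("habitat table has no positive weight")
    out["probability"] = weights / total
    return out


def _pair_distances(points: np.ndarray, rng: np.random.Generator, n: int) -> np.ndarray:
    """Distances of ``n`` uniformly chosen unordered pairs of ``points``."""
    m = len(points)
    i = rng.integers(0, m, size=n)
    j = rng.integers(0, m - 1, size=n)
    j = np.where(j >= i, j + 1, j)  # uniform over pairs with j != i
    return np.linalg.norm(points[i] - points[j], axis=1)


def sample_distances(
    scenario: SpatialScenario,
    n_pulses: int,
    seed: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """Draw ``n_pulses`` inter-individual distances under the scenario.

    Positions are resampled for every pulse, so the stream is i.i.d.;
    temporal correlation of real animal movement is deliberately out of
    scope.  Returns distances in metres, reproducible under a fixed seed.
    """
    if n_pulses < 1:
        raise ValueError("n_pulses must be >= 1")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    if scenario.kind == "uniform-distance":
        u = rng.random(n_pulses)
        return (1.0 - u) * scenario.max_uniform_distance  # uniform on (0, max]
    if scenario.kind == "random-2d":
        # A uniformly chosen pair of fresh uniform points per pulse: the
        # distance follows the square line-picking distribution.
        p = rng.random((n_pulses, 2, 2)) * scenario.area_side
        return np.linalg.norm(p[:, 0] - p[:, 1], axis=1)
    # clustered-groups: resample the whole population per batch, then a
    # random pair per pulse (within- and between-group pairs pooled).
    out = np.empty(n_pulses)
    batch = 10_000
    radius = scenario.group_diameter / 2.0
    for start in range(0, n_pulses, batch):
        k = min(batch, n_pulses - start)
        centers = rng.random((scenario.n_groups, 2)) * scenario.area_side
        ang = rng.random((scenario.n_groups, scenario.group_size)) * 2 * np.pi
        rad = radius * np.sqrt(rng.random((scenario.n_groups, scenario.group_size)))
        offsets = np.stack([rad * np.cos(ang), rad * np.sin(ang)], axis=-1)
        points = (centers[:, None, :] + offsets).reshape(-1, 2)
        out[start : start + k] = _pair_distances(points, rng, k)
    return out


def sample_context(
    table: pd.DataFrame,
    n: int,
    seed: int | np.random.Generator | None = 0,
) -> list[Stratum]:
    """Draw ``n`` habitat-height strata i.i.d. from the preference table.

    Both members of a pulse's tag pair share the drawn stratum — animals
    close enough to exchange pulses occupy the same context.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    norm = normalize_habitat_table(table)
    strata = [
        Stratum(h, Height(z)) for h, z in zip(norm["habitat"], norm["height"])
    ]
    idx = rng.choice(len(strata), size=n, p=norm["probability"].to_numpy())
    return [strata[i] for i in idx]


def simulate_pulses(
    scenario: SpatialScenario,
    table: pd.DataFrame,
    params: dict[Stratum, PropagationParams],
    variances: dict | None = None,
    n_pulses: int = 1_000_000,
    seed: int | np.random.Generator | None = 0,
    persistent_tag_effects: bool = False,
) -> pd.DataFrame:
    """Simulate a wild-pulse population of ``n_pulses`` RSSI values.

    Each pulse draws a distance from the spatial scenario, a stratum from
    the habitat table, independent uniform antenna angles theta and phi,
    and RSSI = expected_rssi + send + receive + exchange + replicate +
    residual with every variance component freshly drawn per pulse (the
    widest-spread reading of per-pulse noise).  With
    ``persistent_tag_effects`` the send/receive draws are instead fixed
    per individual of a virtual population of ``scenario.n_individuals``
    tags and pulses sample sender/receiver pairs from it.

    Returns a DataFrame with columns ``PULSE_COLUMNS``; the stream is
    bit-reproducible under a fixed seed.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    variances = variances or {}
    var_send = float(variances.get("var_send", 0.0))
    var_receive = float(variances.get("var_receive", 0.0))
    cov_sr = float(variances.get("cov_send_receive", 0.0))
    var_ex = variances.get("var_exchange", {})
    var_rep = float(variances.get("var_replicate", 0.0))
    var_res = float(variances.get("var_residual", 0.0))

    r = sample_distances(scenario, n_pulses, rng)
    strata = sample_context(table, n_pulses, rng)
    missing = {s.label for s in strata if s not in params}
    if missing:
        raise ValueError(
            f"missing propagation parameters for stratum/strata: {sorted(missing)}"
        )
    theta = rng.random(n_pulses) * 360.0
    phi = rng.random(n_pulses) * 360.0
    delta = np.asarray(directivity_db(theta, phi))

    kappa = np.array([params[s].kappa for s in strata])
    beta = np.array([params[s].beta for s in strata])
    gamma = np.array([params[s].gamma for s in strata])
    mean = kappa + beta * r - 20.0 * np.log10(r) + gamma * delta

    if persistent_tag_effects:
        cov = np.array([[var_send, cov_sr], [cov_sr, var_receive]])
        w, v = np.linalg.eigh(cov)
        root = v @ np.diag(np.sqrt(np.clip(w, 0, None))) @ v.T
        effects = rng.standard_normal((scenario.n_individuals, 2)) @ root.T
        tx = rng.integers(0, scenario.n_individuals, size=n_pulses)
        shift = 1 + rng.integers(0, scenario.n_individuals - 1, size=n_pulses)
        rx = (tx + shift) % scenario.n_individuals
        send = effects[tx, 0]
        receive = effects[rx, 1]
    else:
        send = rng.normal(0.0, np.sqrt(var_send), n_pulses) if var_send else 0.0
        receive = (
            rng.normal(0.0, np.sqrt(var_receive), n_pulses) if var_receive else 0.0
        )
    sd_ex = np.sqrt(np.array([float(var_ex.get(s.label, 0.0)) for s in strata]))
    exchange = np.where(sd_ex > 0, rng.normal(0.0, 1.0, n_pulses) * sd_ex, 0.0)
    replicate = rng.normal(0.0, np.sqrt(var_rep), n_pulses) if var_rep else 0.0
    residual = rng.normal(0.0, np.sqrt(var_res), n_pulses) if var_res else 0.0

    rssi = mean + send + receive + exchange + replicate + residual
    return pd.DataFrame(
        {
            "r": r,
            "habitat": [s.habitat for s in strata],
            "height": [s.height.value for s in strata],
            "theta": theta,
            "phi": phi,
            "rssi": rssi,
        }
    )
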