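"""Hierarchical calibration model fitted by Markov chain Monte Carlo.

Because distance is known exactly in a calibration array, the spreading
term can be moved to the left-hand side, giving the response

    y_i = RSSI_i + 20 log10 r_i

which is then modelled as a Gaussian linear mixed model::

    y = kappa(h,z) + beta(h,z) r + gamma delta(theta,phi)
        + send(tx) + receive(rx) + exchange(pair; h,z)
        + replicate(directed pair, trial) + eps

Fixed effects: a per-stratum intercept ``kappa``, a per-stratum distance
slope ``beta``, and ``gamma`` scaling the dipole directivity term (a
value of 1 validates the dipole assumption).  Random effects: correlated
per-tag (send, receive) ability drawn from a bivariate normal; a
pair-level ``exchange`` effect with a separate variance per stratum; a
``replicate`` effect per directed pair within a trial; and i.i.d.
residuals.

The sampler is a blocked Gibbs scheme with conjugate updates: normal
draws for fixed and random effects, inverse-gamma draws for scalar
variances, and an inverse-Wishart draw for the 2x2 tag covariance.
Posterior modes are located by Gaussian-kernel density maximisation and
intervals are central 95% quantiles of the retained samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, qr, solve_triangular

from .propagation import Height, Stratum, directivity_db

__all__ = [
    "ModelSpec",
    "McmcSettings",
    "PosteriorSummary",
    "build_response",
    "fit",
    "summarize",
    "prediction_band",
]

Z95 = float(stats.norm.ppf(0.975))  # 1.959964...


@dataclass(frozen=True)
class ModelSpec:
    """Structure switches for the calibration model.

    include_gamma   : estimate the directivity coefficient (else fix at
                      the value in ``fixed_gamma``).
    fixed_gamma     : directivity multiplier used when gamma is not
                      estimated; 1 is the physical-model value.
    """

    include_gamma: bool = True
    fixed_gamma: float = 1.0


@dataclass(frozen=True)
class McmcSettings:
    """Gibbs sampler schedule and prior hyperparameters.

    The default schedule (130 000 iterations, 30 000 burn-in, thin 20)
    retains exactly 5 000 near-independent posterior samples.  Variance
    priors are weakly informative inverse-gamma(shape, scale); the 2x2
    tag covariance gets an inverse-Wishart(df, scale * I) prior; fixed
    effects get independent N(0, fixed_effect_variance) priors.
    """

    n_iterations: int = 130_000
    burn_in: int = 30_000
    thin: int = 20
    seed: int = 0
    fixed_effect_variance: float = 1e8
    variance_shape: float = 0.001
    variance_scale: float = 0.001
    tag_cov_df: float = 3.0
    tag_cov_scale: float = 0.01

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("need 0 <= burn_in < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


@dataclass
class PosteriorSummary:
    """Posterior modes, 95% credible intervals and retained samples.

    ``table`` has one row per parameter (name, mode, lower, upper);
    ``samples`` maps parameter names to retained-sample arrays.  Variance
    components are named ``var_send``, ``var_receive``,
    ``cov_send_receive``, ``corr_send_receive``, ``var_exchange:<label>``,
    ``var_replicate`` and ``var_residual``; fixed effects are
    ``kappa:<label>``, ``beta:<label>`` and ``gamma``.
    """

    table: pd.DataFrame
    samples: dict[str, np.ndarray] = field(default_factory=dict)
    strata: tuple[Stratum, ...] = ()

    def mode(self, name: str) -> float:
        row = self.table.loc[self.table["name"] == name]
        if row.empty:
            raise KeyError(f"no parameter named {name!r}")
        return float(row["mode"].iloc[0])

    def interval(self, name: str) -> tuple[float, float]:
        row = self.table.loc[self.table["name"] == name]
        if row.empty:
            raise KeyError(f"no parameter named {name!r}")
        return float(row["lower"].iloc[0]), float(row["upper"].iloc[0])

    def total_variance(self, stratum: Stratum) -> float:
        """Summed random-effect + residual variance for one stratum (modes).

        Send and receive effects belong to different tags in any one
        pulse, so their variances add without a covariance term.
        """
        key = f"var_exchange:{stratum.label}"
        names = ["var_send", "var_receive", "var_replicate", "var_residual"]
        total = sum(self.mode(n) for n in names)
        if key in set(self.table["name"]):
            total += self.mode(key)
        return total

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", indent=2)


def build_response(rssi, r) -> np.ndarray | float:
    """Construct the model response y = RSSI + 20 log10 r.

    Adding the known spherical-spreading term back onto the observed
    RSSI removes the only nonlinear-in-distance piece, leaving a model
    that is linear in r.  Requires r > 0.
    """
    rr = np.asarray(r, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("distance r must be > 0")
    out = np.asarray(rssi, dtype=float) + 20.0 * np.log10(rr)
    return float(out) if out.ndim == 0 else out


def _design(observations: pd.DataFrame, spec: ModelSpec):
    """Build fixed-effect matrix, effect index arrays and names."""
    obs = observations.reset_index(drop=True)
    strata = sorted(
        {
            Stratum(h, Height(z))
            for h, z in zip(obs["habitat"], obs["height"])
        },
        key=lambda s: s.label,
    )
    stratum_labels = [s.label for s in strata]
    obs_label = (obs["habitat"] + ":" + obs["height"]).to_numpy()
    stratum_idx = np.array([stratum_labels.index(lb) for lb in obs_label])

    n = len(obs)
    S = len(strata)
    r = obs["r"].to_numpy(dtype=float)
    delta = np.asarray(directivity_db(obs["theta"].to_numpy(), obs["phi"].to_numpy()))

    names: list[str] = []
    cols: list[np.ndarray] = []
    for k, lb in enumerate(stratum_labels):
        ind = (stratum_idx == k).astype(float)
        cols.append(ind)
        names.append(f"kappa:{lb}")
    for k, lb in enumerate(stratum_labels):
        ind = (stratum_idx == k).astype(float)
        cols.append(ind * r)
        names.append(f"beta:{lb}")
    offset = np.zeros(n)
    if spec.include_gamma:
        cols.append(delta)
        names.append("gamma")
    else:
        offset = spec.fixed_gamma * delta
    X = np.column_stack(cols)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R, piv = qr(X, mode="economic", pivoting=True)
        tol = abs(R[0, 0]) * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(X.shape[1]) if abs(R[i, i]) <= tol]
        raise ValueError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            f"confounded term(s): {bad}"
        )

    tags = np.unique(
        np.concatenate([obs["sender_id"].to_numpy(), obs["receiver_id"].to_numpy()])
    )
    tag_index = {int(t): i for i, t in enumerate(tags)}
    send_idx = np.array([tag_index[int(t)] for t in obs["sender_id"]])
    recv_idx = np.array([tag_index[int(t)] for t in obs["receiver_id"]])

    pair_key = [
        (min(a, b), max(a, b), lb)
        for a, b, lb in zip(obs["sender_id"], obs["receiver_id"], obs_label)
    ]
    ex_groups = sorted(set(pair_key))
    ex_lookup = {k: i for i, k in enumerate(ex_groups)}
    ex_idx = np.array([ex_lookup[k] for k in pair_key])
    ex_stratum = np.array([stratum_labels.index(k[2]) for k in ex_groups])

    rep_key = obs["replicate_id"].to_numpy()
    rep_groups, rep_idx = np.unique(rep_key, return_inverse=True)

    y = build_response(obs["rssi"].to_numpy(), r)
    return {
        "y": np.asarray(y) - offset,
        "X": X,
        "names": names,
        "strata": tuple(strata),
        "stratum_labels": stratum_labels,
        "send_idx": send_idx,
        "recv_idx": recv_idx,
        "n_tags": len(tags),
        "ex_idx": ex_idx,
        "ex_stratum": ex_stratum,
        "rep_idx": rep_idx,
        "n_rep": len(rep_groups),
    }


def _gibbs(d: dict, spec: ModelSpec, settings: McmcSettings) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(settings.seed)
    y, X = d["y"], d["X"]
    n, p = X.shape
    T = d["n_tags"]
    G = d["ex_idx"].max() + 1
    R = d["n_rep"]
    S = len(d["stratum_labels"])
    send_idx, recv_idx = d["send_idx"], d["recv_idx"]
    ex_idx, rep_idx = d["ex_idx"], d["rep_idx"]
    ex_stratum = d["ex_stratum"]

    n_send = np.bincount(send_idx, minlength=T).astype(float)
    n_recv = np.bincount(recv_idx, minlength=T).astype(float)
    n_ex = np.bincount(ex_idx, minlength=G).astype(float)
    n_rep = np.bincount(rep_idx, minlength=R).astype(float)
    m_ex = np.bincount(ex_stratum, minlength=S).astype(float)
    XtX = X.T @ X

    a0, b0 = settings.variance_shape, settings.variance_scale
    tau2 = settings.fixed_effect_variance
    df0 = settings.tag_cov_df
    S0 = settings.tag_cov_scale * np.eye(2)

    # State initialisation: OLS-ish fixed effects, zero random effects.
    b = np.linalg.lstsq(X, y, rcond=None)[0]
    s = np.zeros(T)
    rc = np.zeros(T)
    e = np.zeros(G)
    rep = np.zeros(R)
    sigma2 = max(float(np.var(y - X @ b)), 1e-6)
    Sigma = np.eye(2)
    var_ex = np.ones(S)
    var_rep = 1.0

    keep = settings.n_retained
    out = {
        "b": np.empty((keep, p)),
        "Sigma": np.empty((keep, 3)),
        "var_ex": np.empty((keep, S)),
        "var_rep": np.empty(keep),
        "sigma2": np.empty(keep),
    }

    def ig(shape, scale):
        return scale / rng.gamma(shape)

    k = 0
    for it in range(settings.n_iterations):
        zu = s[send_idx] + rc[recv_idx] + e[ex_idx] + rep[rep_idx]

        # --- fixed effects (joint normal draw)
        A = XtX / sigma2 + np.eye(p) / tau2
        cf = cho_factor(A, lower=True)
        mean = cho_solve(cf, X.T @ (y - zu) / sigma2)
        z = rng.standard_normal(p)
        b = mean + solve_triangular(np.tril(cf[0]).T, z, lower=False)
        f = X @ b

        # --- tag send effects | receive effects (blocked: senders are
        # unique per row, so all tags update independently here)
        vs, vr, cv = Sigma[0, 0], Sigma[1, 1], Sigma[0, 1]
        c = y - f - rc[recv_idx] - e[ex_idx] - rep[rep_idx]
        sums = np.bincount(send_idx, weights=c, minlength=T)
        if vr > 1e-300:
            prior_mean = (cv / vr) * rc
            prior_var = max(vs - cv**2 / vr, 1e-12)
        else:
            prior_mean = np.zeros(T)
            prior_var = max(vs, 1e-12)
        post_var = 1.0 / (n_send / sigma2 + 1.0 / prior_var)
        post_mean = post_var * (sums / sigma2 + prior_mean / prior_var)
        s = post_mean + np.sqrt(post_var) * rng.standard_normal(T)

        # --- tag receive effects | send effects
        c = y - f - s[send_idx] - e[ex_idx] - rep[rep_idx]
        sums = np.bincount(recv_idx, weights=c, minlength=T)
        if vs > 1e-300:
            prior_mean = (cv / vs) * s
            prior_var = max(vr - cv**2 / vs, 1e-12)
        else:
            prior_mean = np.zeros(T)
            prior_var = max(vr, 1e-12)
        post_var = 1.0 / (n_recv / sigma2 + 1.0 / prior_var)
        post_mean = post_var * (sums / sigma2 + prior_mean / prior_var)
        rc = post_mean + np.sqrt(post_var) * rng.standard_normal(T)

        # --- tag covariance (inverse-Wishart conjugate update)
        U = np.column_stack([s, rc])
        Sigma = stats.invwishart.rvs(
            df=df0 + T, scale=S0 + U.T @ U, random_state=rng
        )

        # --- exchange effects (conditionally independent across pairs)
        c = y - f - s[send_idx] - rc[recv_idx] - rep[rep_idx]
        sums = np.bincount(ex_idx, weights=c, minlength=G)
        pv = var_ex[ex_stratum]
        post_var = 1.0 / (n_ex / sigma2 + 1.0 / pv)
        post_mean = post_var * sums / sigma2
        e = post_mean + np.sqrt(post_var) * rng.standard_normal(G)

        # --- per-stratum exchange variances
        ss_ex = np.bincount(ex_stratum, weights=e**2, minlength=S)
        var_ex = ig(a0 + m_ex / 2.0, b0 + ss_ex / 2.0)

        # --- replicate effects and variance
        c = y - f - s[send_idx] - rc[recv_idx] - e[ex_idx]
        sums = np.bincount(rep_idx, weights=c, minlength=R)
        post_var = 1.0 / (n_rep / sigma2 + 1.0 / var_rep)
        post_mean = post_var * sums / sigma2
        rep = post_mean + np.sqrt(post_var) * rng.standard_normal(R)
        var_rep = float(ig(a0 + R / 2.0, b0 + float(rep @ rep) / 2.0))

        # --- residual variance
        resid = y - f - s[send_idx] - rc[recv_idx] - e[ex_idx] - rep[rep_idx]
        sigma2 = float(ig(a0 + n / 2.0, b0 + float(resid @ resid) / 2.0))

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            if k < keep:
                out["b"][k] = b
                out["Sigma"][k] = (Sigma[0, 0], Sigma[1, 1], Sigma[0, 1])
                out["var_ex"][k] = var_ex
                out["var_rep"][k] = var_rep
                out["sigma2"][k] = sigma2
                k += 1
    return out


def _kde_mode(samples: np.ndarray) -> float:
    """Posterior mode via Gaussian KDE (Silverman bandwidth) on a grid."""
    samples = np.asarray(samples, dtype=float)
    if np.std(samples) == 0:
        return float(samples[0])
    kde = stats.gaussian_kde(samples, bw_method="silverman")
    grid = np.linspace(samples.min(), samples.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def summarize(
    samples: dict[str, np.ndarray], strata: tuple[Stratum, ...] = ()
) -> PosteriorSummary:
    """Summarise retained samples as modes and central 95% intervals.

    Requires at least 100 retained samples per parameter.  If raw
    ``var_send``/``var_receive``/``cov_send_receive`` sample arrays are
    present, the derived ``corr_send_receive`` is appended.
    """
    samples = dict(samples)
    for name, arr in samples.items():
        if len(arr) < 100:
            raise ValueError(
                f"need >= 100 retained samples to summarise, got {len(arr)} "
                f"for {name!r}"
            )
    if (
        "cov_send_receive" in samples
        and "corr_send_receive" not in samples
        and "var_send" in samples
    ):
        denom = np.sqrt(samples["var_send"] * samples["var_receive"])
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(denom > 0, samples["cov_send_receive"] / denom, 0.0)
        samples["corr_send_receive"] = np.clip(corr, -1.0, 1.0)

    rows = []
    for name, arr in samples.items():
        arr = np.asarray(arr, dtype=float)
        mode = _kde_mode(arr)
        lower, upper = np.percentile(arr, [2.5, 97.5])
        mode = float(np.clip(mode, lower, upper))
        rows.append((name, mode, float(lower), float(upper)))
    table = pd.DataFrame(rows, columns=["name", "mode", "lower", "upper"])
    return PosteriorSummary(table=table, samples=samples, strata=strata)


def fit(
    observations: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    settings: McmcSettings = McmcSettings(),
) -> PosteriorSummary:
    """Fit the calibration mixed model by blocked Gibbs sampling.

    ``observations`` is a calibration table in the schema produced by
    :func:`proxcal.synthetic.simulate_calibration` (columns sender_id,
    receiver_id, r, theta, phi, habitat, height, trial_id, replicate_id,
    rssi).  Returns a :class:`PosteriorSummary` over fixed effects and
    variance components; chains are reproducible under a fixed seed.
    """
    if observations["sender_id"].nunique() < 2:
        raise ValueError("need at least 2 distinct tags to fit tag effects")
    d = _design(observations, spec)
    raw = _gibbs(d, spec, settings)

    named: dict[str, np.ndarray] = {}
    for j, name in enumerate(d["names"]):
        named[name] = raw["b"][:, j]
    named["var_send"] = raw["Sigma"][:, 0]
    named["var_receive"] = raw["Sigma"][:, 1]
    named["cov_send_receive"] = raw["Sigma"][:, 2]
    for j, lb in enumerate(d["stratum_labels"]):
        named[f"var_exchange:{lb}"] = raw["var_ex"][:, j]
    named["var_replicate"] = raw["var_rep"]
    named["var_residual"] = raw["sigma2"]
    return summarize(named, strata=d["strata"])


def prediction_band(
    r,
    stratum: Stratum,
    delta,
    summary: PosteriorSummary,
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Central 95% predictive band for RSSI at distance ``r``.

    The band is the fitted mean RSSI (posterior modes) plus/minus 1.96
    times the square root of the summed random-effect + residual
    variance for the stratum; its half-width is constant in r, so both
    edges inherit the mean's monotone decline.
    """
    rr = np.asarray(r, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("distance r must be > 0")
    try:
        kappa = summary.mode(f"kappa:{stratum.label}")
        beta = summary.mode(f"beta:{stratum.label}")
    except KeyError as exc:
        raise ValueError(f"stratum {stratum.label!r} not in fitted model") from exc
    gamma = (
        summary.mode("gamma") if "gamma" in set(summary.table["name"]) else 1.0
    )
    mean = kappa + beta * rr - 20.0 * np.log10(rr) + gamma * np.asarray(delta)
    half = Z95 * np.sqrt(summary.total_variance(stratum))
    lower, upper = mean - half, mean + half
    if np.ndim(lower) == 0:
        return float(lower), float(upper)
    return lower, upper
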