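"""One-site fluorescence-anisotropy binding model and dissociation-constant fits.

A fluorophore-labelled DNA probe at fixed concentration ``T`` is titrated with
protein at total concentrations ``P``; anisotropy interpolates linearly in the
bound probe fraction ``b`` between the free (``r_free``) and bound
(``r_bound``) plateaus.  Because the probe (2 nM) is comparable to the
dissociation constant (~6 nM), ligand depletion matters and ``b`` is the exact
quadratic mass-balance solution

    b = ((P + T + K_D) - sqrt((P + T + K_D)^2 - 4 P T)) / (2 T)

rather than the hyperbola P/(P + K_D), which remains available for comparison
and is recovered in the T -> 0 limit.  Fitting is nonlinear least squares over
(log K_D, r_free, r_bound) with replicates pooled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "TitrationCurve",
    "BindingFit",
    "bound_fraction",
    "model_anisotropy",
    "simulate_titration",
    "fit_titration",
    "default_titration_grid",
]


def bound_fraction(P, T: float, K_D: float, model: str = "quadratic"):
    """Fraction of probe bound at total titrant P, probe T, constant K_D.

    ``model="quadratic"`` is the exact depletion-corrected single-site
    solution; ``model="hyperbolic"`` ignores depletion (b = P/(P+K_D)).
    Accepts scalars or arrays of P.
    """
    P = np.asarray(P, dtype=float)
    if np.any(P < 0) or K_D < 0:
        raise ValueError("concentrations must be >= 0")
    if T <= 0:
        raise ValueError("probe concentration T must be > 0")
    if model == "hyperbolic":
        b = P / (P + K_D)
    elif model == "quadratic":
        s = P + T + K_D
        disc = s * s - 4.0 * P * T
        # analytically >= (P+T-K_D)^2 >= 0; clip guards rounding
        b = (s - np.sqrt(np.clip(disc, 0.0, None))) / (2.0 * T)
    else:
        raise ValueError(f"unknown model {model!r}")
    return b if b.ndim else float(b)


def model_anisotropy(P, params: dict, T: float, model: str = "quadratic"):
    """r = r_free + (r_bound - r_free) * b(P, T, K_D)."""
    b = bound_fraction(P, T, params["K_D"], model=model)
    return params["r_free"] + (params["r_bound"] - params["r_free"]) * b


def default_titration_grid(
    K_D: float,
    T: float = 2.0,
    start: float = 6.2,
    saturation: float = 0.98,
    include_zero: bool = True,
    max_points: int = 20,
) -> np.ndarray:
    """Doubling dilution series from ``start`` until the probe is saturated.

    Mirrors the titration protocol: successive protein additions starting at
    6.2 nM until anisotropy saturates (bound fraction > ``saturation`` at the
    stated ground truth).  A protein-free baseline point anchors ``r_free``.
    """
    grid = [0.0] if include_zero else []
    conc = start
    for _ in range(max_points):
        grid.append(conc)
        if bound_fraction(conc, T, K_D) > saturation:
            break
        conc *= 2.0
    return np.array(grid)


@dataclass
class TitrationCurve:
    """Concentration-anisotropy data (replicates long-form)."""

    probe_nM: float
    table: pd.DataFrame  # columns: P_nM, anisotropy, replicate
    condition: str = "dark"
    variant: str = ""

    def __post_init__(self) -> None:
        if self.probe_nM <= 0:
            raise ValueError("probe_nM must be > 0")
        required = {"P_nM", "anisotropy", "replicate"}
        if not required <= set(self.table.columns):
            raise ValueError(f"titration table needs columns {sorted(required)}")
        if (self.table["P_nM"] < 0).any():
            raise ValueError("negative titrant concentration")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# probe_nM: {self.probe_nM}\n")
            fh.write(f"# condition: {self.condition}\n")
            fh.write(f"# variant: {self.variant}\n")
            self.table.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, probe_nM: float | None = None) -> "TitrationCurve":
        meta: dict[str, str] = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                k, v = line[1:].split(":", 1)
                meta[k.strip()] = v.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh, sep="\t")
        if "replicate" not in df.columns:
            df["replicate"] = 0
        return cls(
            probe_nM=probe_nM if probe_nM is not None else float(meta.get("probe_nM", 2.0)),
            table=df,
            condition=meta.get("condition", "dark"),
            variant=meta.get("variant", ""),
        )


@dataclass
class BindingFit:
    K_D: float
    r_free: float
    r_bound: float
    se_K_D: float
    se_r_free: float
    se_r_bound: float
    residual_rms: float
    converged: bool
    model: str = "quadratic"
    n_points: int = 0
    message: str = ""


def simulate_titration(
    params: dict,
    T: float = 2.0,
    P_grid=None,
    noise_sd: float = 0.005,
    n_replicates: int = 2,
    seed: int = 0,
    condition: str = "dark",
    variant: str = "",
    model: str = "quadratic",
) -> TitrationCurve:
    """Model anisotropies plus i.i.d. Gaussian noise; deterministic given seed.

    With ``P_grid=None`` the default doubling series from 6.2 nM is generated
    from the ground-truth K_D in ``params``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if P_grid is None:
        P_grid = default_titration_grid(params["K_D"], T=T)
    P_grid = np.asarray(P_grid, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        r = model_anisotropy(P_grid, params, T, model=model)
        if noise_sd > 0:
            r = r + rng.normal(0.0, noise_sd, size=P_grid.size)
        for Pv, rv in zip(P_grid, r):
            rows.append({"P_nM": Pv, "anisotropy": rv, "replicate": rep})
    return TitrationCurve(
        probe_nM=T,
        table=pd.DataFrame(rows),
        condition=condition,
        variant=variant,
    )


def _initial_guess(P: np.ndarray, r: np.ndarray) -> tuple[float, float, float]:
    order = np.argsort(P)
    P, r = P[order], r[order]
    r_free0 = float(np.mean(r[P == P.min()]))
    r_bound0 = float(np.mean(r[P == P.max()]))
    mid = (r_free0 + r_bound0) / 2.0
    above = P[r >= mid] if r_bound0 > r_free0 else P[r <= mid]
    nonzero = above[above > 0]
    K0 = float(nonzero.min()) if nonzero.size else float(np.median(P[P > 0]))
    return max(K0, 1e-6), r_free0, r_bound0


def fit_titration(curve: TitrationCurve, model: str = "quadratic") -> BindingFit:
    """Pooled nonlinear least-squares fit of (K_D, r_free, r_bound).

    K_D is log-parameterised to enforce positivity; endpoints of the curve
    initialise the plateaus and the half-rise concentration initialises K_D.
    Standard errors come from the Jacobian at the optimum.  Non-convergence
    or a boundary K_D sets ``converged=False`` (never silently hidden).
    """
    P = curve.table["P_nM"].to_numpy(dtype=float)
    r = curve.table["anisotropy"].to_numpy(dtype=float)
    if np.unique(P).size < 4:
        raise ValueError("need >= 4 distinct titrant concentrations for identifiability")
    T = curve.probe_nM

    K0, rf0, rb0 = _initial_guess(P, r)
    x0 = np.array([np.log(K0), rf0, rb0])

    def resid(x):
        params = {"K_D": np.exp(x[0]), "r_free": x[1], "r_bound": x[2]}
        return model_anisotropy(P, params, T, model=model) - r

    sol = least_squares(resid, x0, method="lm", max_nfev=10_000)
    K_D = float(np.exp(sol.x[0]))
    dof = max(P.size - 3, 1)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    s2 = float(np.sum(sol.fun**2) / dof)
    J = sol.jac
    try:
        cov = np.linalg.inv(J.T @ J) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(3, np.nan)
    se_K = K_D * se[0]  # delta method on log K_D

    boundary = not (1e-6 < K_D < 1e8)
    converged = bool(sol.success and not boundary and np.isfinite(K_D))
    return BindingFit(
        K_D=K_D,
        r_free=float(sol.x[1]),
        r_bound=float(sol.x[2]),
        se_K_D=float(se_K),
        se_r_free=float(se[1]),
        se_r_bound=float(se[2]),
        residual_rms=rms,
        converged=converged,
        model=model,
        n_points=int(P.size),
        message=str(sol.message),
    )
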