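"""Seeded generators for benchmark dynamics and full synthetic studies.

Three levels:

* :func:`gen_coupled_logistic` — the classic coupled logistic-map benchmark
  for cross-mapping directionality.
* :func:`gen_var_pair` — a bivariate VAR(1) for Granger calibration.
* :func:`gen_synthetic_study` — a complete study: negative-binomial count
  expression with per-sample depth factors, a target metabolite driven by a
  small set of genes through a lagged saturating response, plus decoy
  metabolites for network tests.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from lagmine.io import OmicsMatrix, write_matrix

__all__ = [
    "SyntheticStudy",
    "gen_coupled_logistic",
    "gen_var_pair",
    "gen_synthetic_study",
    "write_study",
    "make_annotation_table",
]

_NB_DISPERSION = 0.05  # fixed over-dispersion of the count model

_ENZYME_WORDS = [
    "acyl-transferase",
    "terpene synthase",
    "cytochrome oxidase",
    "alcohol dehydrogenase",
    "protein kinase",
]
_OTHER_WORDS = [
    "ribosomal protein L3",
    "histone H2A",
    "transport protein",
    "transcription factor bZIP",
]


@dataclasses.dataclass
class SyntheticStudy:
    expression: OmicsMatrix
    metabolites: OmicsMatrix
    truth: list[dict]  # [{"gene", "lag", "effect"}, ...]
    seed: int
    target_id: str = "met_target"
    depth_factors: np.ndarray | None = None


def gen_coupled_logistic(
    N: int,
    r_x: float = 3.8,
    r_y: float = 3.5,
    beta_xy: float = 0.0,
    beta_yx: float = 0.0,
    x0: float | None = None,
    y0: float | None = None,
    seed: int = 0,
    burn_in: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Two coupled logistic maps; ``beta_xy`` is the x -> y coupling strength.

    x_{t+1} = x_t (r_x (1 - x_t) - beta_yx y_t)
    y_{t+1} = y_t (r_y (1 - y_t) - beta_xy x_t)

    The first ``burn_in`` steps are discarded. Raises if the trajectory
    escapes [0, 1] ("unstable parameters").
    """
    if not (3.5 <= r_x <= 4.0 and 3.5 <= r_y <= 4.0):
        raise ValueError("growth rates must lie in [3.5, 4.0]")
    if not (0 <= beta_xy < 1 and 0 <= beta_yx < 1):
        raise ValueError("couplings must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    x = float(x0) if x0 is not None else float(rng.uniform(0.1, 0.9))
    y = float(y0) if y0 is not None else float(rng.uniform(0.1, 0.9))
    if not (0 < x < 1 and 0 < y < 1):
        raise ValueError("initial conditions must lie in (0, 1)")
    xs = np.empty(N)
    ys = np.empty(N)
    for t in range(burn_in + N):
        x_new = x * (r_x * (1 - x) - beta_yx * y)
        y_new = y * (r_y * (1 - y) - beta_xy * x)
        if not (0.0 <= x_new <= 1.0 and 0.0 <= y_new <= 1.0):
            raise ValueError("unstable parameters: trajectory escaped [0, 1]")
        x, y = x_new, y_new
        if t >= burn_in:
            xs[t - burn_in] = x
            ys[t - burn_in] = y
    return xs, ys


def gen_var_pair(
    N: int,
    a_xx: float = 0.5,
    a_yx: float = 0.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate VAR(1): x drives y with coefficient ``a_yx``.

    x_t = a_xx x_{t-1} + eps;  y_t = a_yx x_{t-1} + a_xx y_{t-1} + eps'
    """
    A = np.array([[a_xx, 0.0], [a_yx, a_xx]])
    if np.max(np.abs(np.linalg.eigvals(A))) >= 1.0:
        raise ValueError("nonstationary parameters: spectral radius >= 1")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd, size=(N + 50, 2))
    z = np.zeros(2)
    xs = np.empty(N)
    ys = np.empty(N)
    for t in range(N + 50):
        z = A @ z + eps[t]
        if t >= 50:
            xs[t - 50] = z[0]
            ys[t - 50] = z[1]
    return xs, ys


def _smooth_trajectory(rng: np.random.Generator, T: int, n_harmonics: int = 3) -> np.ndarray:
    """Mean-zero smooth latent trajectory from a few random Fourier modes."""
    t = np.arange(T)
    out = np.zeros(T)
    for h in range(1, n_harmonics + 1):
        amp = rng.normal(0.0, 0.25 / h**2)
        phase = rng.uniform(0.0, 2 * np.pi)
        out += amp * np.sin(2 * np.pi * h * t / T + phase)
    return out


def _pulse_trajectory(rng: np.random.Generator, T: int, amplitude: float) -> np.ndarray:
    """A smooth single pulse peaking mid-course (the driver signature)."""
    t = np.arange(T)
    center = rng.uniform(0.35 * T, 0.6 * T)
    width = max(T / 6.0, 1.0)
    return amplitude * np.exp(-0.5 * ((t - center) / width) ** 2)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray) -> np.ndarray:
    """Negative-binomial draws with fixed dispersion (var = mu + disp*mu^2)."""
    n = 1.0 / _NB_DISPERSION
    mean = np.maximum(mean, 1e-8)
    p = n / (n + mean)
    return rng.negative_binomial(n, p).astype(float)


def gen_synthetic_study(
    G: int = 100,
    T: int = 13,
    R: int = 3,
    n_drivers: int = 1,
    lag: int = 1,
    effect: float = 2.5,
    depth_spread: float = 0.3,
    seed: int = 0,
    n_decoy_metabolites: int = 8,
    met_noise: float = 0.02,
) -> SyntheticStudy:
    """Generate a full study with known driver genes.

    Driver genes carry a smooth latent pulse of log-amplitude ``effect``; the
    target metabolite is a saturating function of the summed driver signal
    ``lag`` steps earlier, plus Gaussian noise. Counts are negative binomial
    around depth_j * exp(latent); depth factors are log-normal with
    log-scale sd ``depth_spread``. Decoy metabolites correlate with the
    target at assorted strengths for network testing.
    """
    if G < 20:
        raise ValueError("G must be >= 20")
    if not 5 <= T <= 40:
        raise ValueError("T must be in [5, 40]")
    if R < 1:
        raise ValueError("R must be >= 1")
    if n_drivers < 0 or n_drivers > G // 2:
        raise ValueError("n_drivers out of range")
    if lag >= T / 2 or lag < 0:
        raise ValueError("lag must satisfy 0 <= lag < T/2")

    for attempt in range(10):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        study = _generate_once(
            rng, G, T, R, n_drivers, lag, effect, depth_spread,
            n_decoy_metabolites, met_noise, seed,
        )
        if study is not None:
            return study
    raise ValueError("could not generate a non-constant target metabolite in 10 tries")


def _generate_once(
    rng, G, T, R, n_drivers, lag, effect, depth_spread, n_decoys, met_noise, seed
):
    gene_ids = [f"g{i:04d}" for i in range(G)]
    drivers = sorted(rng.choice(G, size=n_drivers, replace=False).tolist())

    base = rng.normal(4.0, 0.5, size=G)
    latent = np.empty((G, T))
    for g in range(G):
        if g in drivers:
            latent[g] = base[g] + _pulse_trajectory(rng, T, effect)
        else:
            latent[g] = base[g] + _smooth_trajectory(rng, T)

    n_samples = T * R
    depth = np.exp(rng.normal(0.0, depth_spread, size=n_samples))
    sample_ids, time_labels, rep_labels = [], [], []
    counts = np.empty((G, n_samples))
    col = 0
    for t in range(T):
        for r in range(1, R + 1):
            sample_ids.append(f"T{t:02d}_r{r}")
            time_labels.append(f"T{t:02d}")
            rep_labels.append(str(r))
            counts[:, col] = _nb_counts(rng, depth[col] * np.exp(latent[:, t]))
            col += 1

    # target metabolite: saturating response to the lagged driver signal
    if n_drivers > 0:
        drive = np.zeros(T)
        for t in range(T):
            t_src = max(t - lag, 0)
            drive[t] = sum(np.exp(latent[g, t_src] - base[g]) - 1.0 for g in drivers)
        drive = np.maximum(drive, 0.0)
        half_sat = max(float(drive.max()), 1e-6)  # mild saturation, shape-preserving
        target = 100.0 * drive / (half_sat + drive)
    else:
        target = np.abs(rng.normal(10.0, 2.0, size=T))
    target = target + rng.normal(0.0, met_noise * max(target.max(), 1.0), size=T)
    target = np.maximum(target, 0.0)
    if np.ptp(target) < 1e-9:
        return None

    met_ids = ["met_target"] + [f"met_decoy{i:02d}" for i in range(n_decoys)]
    tz = target - target.mean()
    tsd = tz.std() if tz.std() > 0 else 1.0
    tz = tz / tsd
    met_latent = [target]
    decoy_corrs = np.linspace(0.95, 0.1, n_decoys) if n_decoys else []
    for rho in decoy_corrs:
        noise = _smooth_trajectory(rng, T) + rng.normal(0, 0.3, size=T)
        nz = noise - noise.mean()
        nsd = nz.std() if nz.std() > 0 else 1.0
        nz = nz / nsd
        mixed = rho * tz + np.sqrt(max(1 - rho**2, 0.0)) * nz
        met_latent.append(np.maximum(20.0 + 6.0 * mixed, 0.0))
    met_latent = np.asarray(met_latent)

    met_samples, met_times, met_reps = [], [], []
    met_values = np.empty((len(met_ids), n_samples))
    col = 0
    for t in range(T):
        for r in range(1, R + 1):
            met_samples.append(f"T{t:02d}_r{r}")
            met_times.append(f"T{t:02d}")
            met_reps.append(str(r))
            jitter = 1.0 + rng.normal(0.0, 0.03, size=len(met_ids))
            met_values[:, col] = np.maximum(met_latent[:, t] * jitter, 0.0)
            col += 1

    expression = OmicsMatrix(
        feature_ids=gene_ids,
        sample_ids=sample_ids,
        values=counts,
        time_labels=time_labels,
        replicate_labels=rep_labels,
    )
    metabolites = OmicsMatrix(
        feature_ids=met_ids,
        sample_ids=met_samples,
        values=met_values,
        time_labels=met_times,
        replicate_labels=met_reps,
    )
    truth = [
        {"gene": gene_ids[g], "lag": int(lag), "effect": float(effect)} for g in drivers
    ]
    return SyntheticStudy(
        expression=expression,
        metabolites=metabolites,
        truth=truth,
        seed=seed,
        depth_factors=depth,
    )


def make_annotation_table(study: SyntheticStudy, rng_seed: int = 0) -> dict[str, str]:
    """Plausible free-text annotations: drivers get enzyme-like descriptions,
    a fifth of the rest are 'hypothetical protein', the others housekeeping."""
    rng = np.random.default_rng(rng_seed)
    driver_genes = {t["gene"] for t in study.truth}
    table: dict[str, str] = {}
    for gid in study.expression.feature_ids:
        if gid in driver_genes:
            table[gid] = str(rng.choice(_ENZYME_WORDS))
        elif rng.uniform() < 0.2:
            table[gid] = "hypothetical protein"
        else:
            table[gid] = str(rng.choice(_OTHER_WORDS))
    return table


def write_study(study: SyntheticStudy, outdir) -> list[Path]:
    """Write expression.csv, metabolites.csv and truth.json into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr_path = outdir / "expression.csv"
    met_path = outdir / "metabolites.csv"
    truth_path = outdir / "truth.json"
    write_matrix(study.expression, expr_path)
    write_matrix(study.metabolites, met_path)
    truth_path.write_text(
        json.dumps(
            {"seed": study.seed, "target": study.target_id, "drivers": study.truth},
            indent=2,
        )
        + "\n"
    )
    return [expr_path, met_path, truth_path]
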