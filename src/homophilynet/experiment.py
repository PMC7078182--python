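"""Fertility sweep: the λ-dependent clustering transition.

Varying fertility changes how many relatives are available, which after
friendship filling changes λ, the fraction of contacts that are friends. The
sweep generates one kin network per (fertility level, replicate), assigns
traits once, and runs every requested friend-choice algorithm on independent
copies of that same network — a paired design that removes the kin-draw
variance from algorithm comparisons. Each run yields one record of λ and the
χ variants; binned curves of χ against λ then show the transition shape:
monotone decline for random friend choice, a u-shaped fall-then-rise when
homophily drives the choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .friendship import ALGORITHMS, Algorithm, CostParams, SocialNetwork, fill_friendships
from .metrics import summarise
from .pedigree import PedigreeParams, assign_traits, generate_pedigree

__all__ = [
    "SweepConfig",
    "SweepRecord",
    "SweepResult",
    "run_sweep",
    "detect_ushape",
    "bin_by_lambda",
    "plot_transition",
    "reduced_scale_config",
    "transition_checks",
]

_ALGO_INDEX = {name: k for k, name in enumerate(ALGORITHMS)}


def default_fertility_grid(n_levels: int = 12, low: float = 1.0, high: float = 8.0) -> list[float]:
    """Log-spaced fertility levels spanning the kin-rich to kin-poor regimes."""
    return [float(x) for x in np.geomspace(low, high, n_levels)]


@dataclass(frozen=True)
class SweepConfig:
    """Parameters of one fertility sweep.

    The default grid of 12 log-spaced fertility levels in [1, 8] spans
    realised λ from roughly 0.3 up to 1.0 at the full scale (n=500, ν=60);
    λ is always measured from the completed networks, never assumed from
    fertility. ``base_seed`` drives every random stream; per-run streams are
    derived from it with a stable spawn key of (level, replicate, algorithm).
    """

    fertility_grid: tuple[float, ...] = tuple(default_fertility_grid())
    replicates_per_level: int = 10
    algorithms: tuple[Algorithm, ...] = ALGORITHMS
    n: int = 500
    nu: int = 60
    cost_params: CostParams = field(default_factory=CostParams)
    family_size_law: str = "binomial"
    trait_low: float = 0.0
    trait_high: float = 100.0
    base_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.fertility_grid) == 0:
            raise ValueError("fertility grid must be non-empty")
        if list(self.fertility_grid) != sorted(self.fertility_grid):
            raise ValueError("fertility grid must be sorted ascending")
        if self.replicates_per_level < 1:
            raise ValueError("replicates_per_level must be >= 1")
        unknown = set(self.algorithms) - set(ALGORITHMS)
        if unknown or not self.algorithms:
            raise ValueError(f"algorithms must be a non-empty subset of {ALGORITHMS}")


def reduced_scale_config(
    base_seed: int = 0,
    nu: int = 20,
    cost_params: CostParams | None = None,
    algorithms: tuple[Algorithm, ...] = ALGORITHMS,
    replicates_per_level: int = 10,
) -> "SweepConfig":
    """Desk-scale sweep: n=200, 12 fertility levels, 10 paired replicates.

    The grid is log-spaced on [0.5, 8] rather than the full-scale [1, 8]: with
    the smaller degree target the kin share of edges is larger at any given
    fertility, so the lower bound drops to keep the realised λ range spanning
    up to ≈ 1, matching the full-scale study's coverage.
    """
    return SweepConfig(
        fertility_grid=tuple(default_fertility_grid(12, 0.5, 8.0)),
        replicates_per_level=replicates_per_level,
        algorithms=algorithms,
        n=200,
        nu=nu,
        cost_params=cost_params if cost_params is not None else CostParams(),
        base_seed=base_seed,
    )


@dataclass(frozen=True)
class SweepRecord:
    """Outcome of one (fertility, replicate, algorithm) run."""

    fertility: float
    replicate: int
    algorithm: str
    lambda_friend_ratio: float
    chi_nu_nsq: float
    chi_nu: float
    chi_local: float
    n: int
    nu: int
    seed: int


@dataclass
class SweepResult:
    """All records of a sweep, one per (level × replicate × algorithm)."""

    records: list[SweepRecord]
    config: SweepConfig

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(r) for r in self.records])
        return df.rename(columns={"lambda_friend_ratio": "lambda"})

    def for_algorithm(self, algorithm: str) -> list[SweepRecord]:
        return [r for r in self.records if r.algorithm == algorithm]


def _run_seed(base_seed: int, level: int, replicate: int, algorithm: int | None) -> int:
    """Stable per-run seed below 2^31, derived from the base seed.

    ``algorithm=None`` keys the shared kin-network/trait draw of the pair
    design; algorithm-specific streams are independent of it.
    """
    key = (level, replicate, 3 if algorithm is None else algorithm)
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=key)
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def simulate_one(
    fertility: float,
    algorithm: Algorithm,
    n: int = 500,
    nu: int = 60,
    cost_params: CostParams = CostParams(),
    family_size_law: str = "binomial",
    trait_low: float = 0.0,
    trait_high: float = 100.0,
    kin_seed: int = 0,
    fill_seed: int = 1,
) -> SocialNetwork:
    """Generate one kin network, assign traits, and fill friendships."""
    kin = generate_pedigree(
        PedigreeParams(n_egos=n, fertility=fertility, family_size_law=family_size_law,
                       seed=kin_seed)
    )
    kin = assign_traits(kin, trait_low, trait_high, seed=kin_seed + 1)
    social = SocialNetwork.from_kin(kin, nu=nu)
    return fill_friendships(social, algorithm=algorithm, params=cost_params,
                            rng=fill_seed)


def run_sweep(config: SweepConfig, progress: bool = False) -> SweepResult:
    """Execute the full sweep; deterministic given ``config.base_seed``."""
    records: list[SweepRecord] = []
    for level, fertility in enumerate(config.fertility_grid):
        for rep in range(config.replicates_per_level):
            kin_seed = _run_seed(config.base_seed, level, rep, None)
            kin = generate_pedigree(
                PedigreeParams(
                    n_egos=config.n,
                    fertility=fertility,
                    family_size_law=config.family_size_law,
                    seed=kin_seed,
                )
            )
            kin = assign_traits(kin, config.trait_low, config.trait_high,
                                seed=kin_seed + 1)
            base = SocialNetwork.from_kin(kin, nu=config.nu)
            for algo in config.algorithms:
                fill_seed = _run_seed(config.base_seed, level, rep, _ALGO_INDEX[algo])
                filled = fill_friendships(
                    base, algorithm=algo, params=config.cost_params, rng=fill_seed
                )
                s = summarise(filled)
                records.append(
                    SweepRecord(
                        fertility=fertility,
                        replicate=rep,
                        algorithm=algo,
                        lambda_friend_ratio=s.lambda_friend_ratio,
                        chi_nu_nsq=s.chi_nu_nsq,
                        chi_nu=s.chi_nu,
                        chi_local=s.chi_local,
                        n=s.n,
                        nu=s.nu,
                        seed=fill_seed,
                    )
                )
            if progress:
                print(f"fertility={fertility:.3g} replicate={rep} done", flush=True)
    return SweepResult(records=records, config=config)


def bin_by_lambda(
    records: Sequence[SweepRecord],
    n_bins: int = 10,
    chi: str = "chi_local",
) -> pd.DataFrame:
    """Equal-width λ bins over the realised range, with per-bin χ mean/count.

    Returns a frame with one row per non-empty bin: bin centre, mean χ,
    record count, and within-bin variance (ddof=1; NaN for singleton bins).
    """
    lam = np.array([r.lambda_friend_ratio for r in records])
    chis = np.array([getattr(r, chi) for r in records])
    lo, hi = lam.min(), lam.max()
    if hi <= lo:
        edges = np.array([lo - 0.5, lo + 0.5])
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(lam, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        mask = idx == b
        if not mask.any():
            continue
        vals = chis[mask]
        rows.append(
            {
                "bin": b,
                "lambda_center": (edges[b] + edges[b + 1]) / 2,
                "lambda_mean": lam[mask].mean(),
                "chi_mean": vals.mean(),
                "count": int(mask.sum()),
                "chi_var": float(vals.var(ddof=1)) if len(vals) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def detect_ushape(
    records: Sequence[SweepRecord],
    n_bins: int = 10,
    chi: str = "chi_local",
    se_margin: float = 2.0,
) -> dict:
    """Test whether χ as a function of λ falls then rises (u-shape).

    Records are binned by λ; the curve is u-shaped when the bin minimising
    mean χ is interior and the first and last bins each exceed the trough by
    more than ``se_margin`` pooled standard errors. Within-bin variance is
    pooled across bins so singleton bins still get a standard error.
    """
    binned = bin_by_lambda(records, n_bins=n_bins, chi=chi)
    if len(binned) < 5:
        raise ValueError("u-shape detection needs at least 5 non-empty lambda bins")
    means = binned["chi_mean"].to_numpy()
    counts = binned["count"].to_numpy()
    variances = binned["chi_var"].to_numpy()
    # pooled within-bin variance over bins with >1 record
    mask = counts > 1
    if mask.any():
        pooled_var = float(
            np.nansum(variances[mask] * (counts[mask] - 1)) / np.sum(counts[mask] - 1)
        )
    else:
        pooled_var = 0.0
    trough = int(np.argmin(means))
    trough_lambda = float(binned["lambda_center"].iloc[trough])

    def exceeds(k: int) -> bool:
        se = np.sqrt(pooled_var / counts[k] + pooled_var / counts[trough])
        return means[k] - means[trough] > se_margin * se

    interior = 0 < trough < len(binned) - 1
    is_ushaped = bool(interior and exceeds(0) and exceeds(len(binned) - 1))
    return {
        "trough_lambda": trough_lambda,
        "is_ushaped": is_ushaped,
        "bin_means": means,
        "bin_counts": counts,
    }


def transition_checks(
    records: Sequence[SweepRecord],
    lambda_high: float = 0.9,
    n_bins: int = 10,
    chi: str = "chi_local",
) -> dict:
    """The transition-curve comparisons between the three algorithms.

    Returns a dict with, per algorithm, the mean χ over high-λ records
    (λ > ``lambda_high``) and the u-shape diagnosis; plus the homophily and
    weighted lifts over random at high λ in pooled-standard-error units, the
    Spearman correlation of random's binned χ against λ, and the fraction of
    shared λ bins in which weighted χ is at least the pure-homophily χ.
    """
    by_algo = {a: [r for r in records if r.algorithm == a] for a in ALGORITHMS}
    out: dict = {"high_lambda_chi": {}, "ushape": {}}

    def chis(recs):
        return np.array([getattr(r, chi) for r in recs])

    high = {
        a: chis([r for r in recs if r.lambda_friend_ratio > lambda_high])
        for a, recs in by_algo.items()
    }
    for a, vals in high.items():
        out["high_lambda_chi"][a] = float(vals.mean()) if vals.size else np.nan
        out.setdefault("high_lambda_n", {})[a] = int(vals.size)
    for a in ("homophily", "weighted"):
        va, vr = high[a], high["random"]
        if va.size > 1 and vr.size > 1:
            se = np.sqrt(va.var(ddof=1) / va.size + vr.var(ddof=1) / vr.size)
            out[f"{a}_lift_se_units"] = float((va.mean() - vr.mean()) / se)
        else:
            out[f"{a}_lift_se_units"] = np.nan

    for a, recs in by_algo.items():
        if recs:
            out["ushape"][a] = detect_ushape(recs, n_bins=n_bins, chi=chi)

    random_recs = by_algo["random"]
    if random_recs:
        binned = bin_by_lambda(random_recs, n_bins=n_bins, chi=chi)
        from scipy import stats as _stats

        out["random_spearman"] = float(
            _stats.spearmanr(binned["lambda_center"], binned["chi_mean"]).statistic
        )

    # weighted-vs-homophily per bin over the shared realised lambda range
    hom, wei = by_algo["homophily"], by_algo["weighted"]
    if hom and wei:
        lam_all = np.array([r.lambda_friend_ratio for r in hom + wei])
        edges = np.linspace(lam_all.min(), lam_all.max(), n_bins + 1)

        def bin_means(recs):
            lam = np.array([r.lambda_friend_ratio for r in recs])
            vals = chis(recs)
            idx = np.clip(np.digitize(lam, edges) - 1, 0, n_bins - 1)
            return {
                b: vals[idx == b].mean() for b in range(n_bins) if (idx == b).any()
            }

        mh, mw = bin_means(hom), bin_means(wei)
        shared = sorted(set(mh) & set(mw))
        wins = sum(1 for b in shared if mw[b] >= mh[b])
        out["weighted_ge_homophily_bin_fraction"] = wins / len(shared) if shared else np.nan
        out["n_shared_bins"] = len(shared)
    return out


_ALGO_COLORS = {"homophily": "tab:orange", "weighted": "tab:green", "random": "tab:blue"}


def plot_transition(result: SweepResult, path: str, chi: str = "chi_local") -> None:
    """Scatter of χ against λ, one colour per algorithm; writes an image file."""
    if not result.records:
        raise ValueError("cannot plot an empty sweep result")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for algo in result.config.algorithms:
        recs = result.for_algorithm(algo)
        if not recs:
            continue
        lam = [r.lambda_friend_ratio for r in recs]
        chis = [getattr(r, chi) for r in recs]
        ax.scatter(lam, chis, s=12, alpha=0.6, color=_ALGO_COLORS[algo], label=algo)
        binned = bin_by_lambda(recs, chi=chi)
        ax.plot(binned["lambda_mean"], binned["chi_mean"], color=_ALGO_COLORS[algo])
    ax.set_xlabel("λ  (fraction of contacts that are friends)")
    ax.set_ylabel(f"clustering coefficient ({chi})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
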