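"""Multi-chain posterior sampling over a model's unconstrained space.

A model object exposes a :class:`~jackrun.infer.transforms.ParameterSpace`,
a ``logp_grad(z)`` callable on the unconstrained vector, and a data-informed
``initial_params()`` dict.  Chains are seeded independently from the run
seed, so a (data, config, seed) triple reproduces draws exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .diagnostics import diagnostics_table
from .nuts import NUTSOptions, nuts_chain

__all__ = ["SamplerConfig", "PosteriorDraws", "sample_posterior", "PRESETS"]


@dataclass(frozen=True)
class SamplerConfig:
    """HMC run settings.

    ``n_iterations`` counts all iterations per chain; the first
    ``warmup_fraction`` are adaptation and are discarded, and one of every
    ``thin`` post-warmup draws is kept.
    """

    n_chains: int = 4
    n_iterations: int = 2000
    warmup_fraction: float = 0.5
    thin: int = 1
    seed: int = 0
    target_accept: float = 0.8
    max_treedepth: int = 8

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not 0 < self.warmup_fraction < 1:
            raise ValueError("warmup_fraction must be in (0, 1)")
        if self.n_warmup >= self.n_iterations:
            raise ValueError("iterations must exceed warmup")

    @property
    def n_warmup(self) -> int:
        return int(self.n_iterations * self.warmup_fraction)

    @property
    def n_keep(self) -> int:
        return (self.n_iterations - self.n_warmup + self.thin - 1) // self.thin


#: Named presets: `test` for desk-scale runs, `paper` for full-length chains
#: (four chains of 30,000, half warmup, keeping every fifth draw).
PRESETS = {
    "test": SamplerConfig(n_chains=4, n_iterations=2000, warmup_fraction=0.5, thin=1),
    "paper": SamplerConfig(n_chains=4, n_iterations=30000, warmup_fraction=0.5, thin=5),
}


@dataclass
class PosteriorDraws:
    """Constrained posterior draws indexed by (chain, draw, ...)."""

    posterior: dict[str, np.ndarray]
    sample_stats: dict[str, np.ndarray]
    config: SamplerConfig
    attrs: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.posterior.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.posterior.values())).shape[1]

    def flat(self, name: str) -> np.ndarray:
        """Draws of one block pooled over chains: (chain*draw, *shape)."""
        x = self.posterior[name]
        return x.reshape(-1, *x.shape[2:])

    def iter_scalars(self):
        """Yield (label, (chain, draw) array) for every scalar component."""
        for name, x in self.posterior.items():
            if x.ndim == 2:
                yield name, x
            else:
                flat = x.reshape(x.shape[0], x.shape[1], -1)
                shape = x.shape[2:]
                for j in range(flat.shape[2]):
                    idx = np.unravel_index(j, shape)
                    label = name + "[" + ",".join(str(i) for i in idx) + "]"
                    yield label, flat[:, :, j]

    def scalar(self, label: str) -> np.ndarray:
        for name, x in self.iter_scalars():
            if name == label:
                return x
        raise KeyError(f"unknown parameter {label!r}")

    @property
    def divergences(self) -> int:
        return int(self.sample_stats["diverging"].sum())

    def diagnostics(self):
        return diagnostics_table(self)

    def to_inference_data(self):
        import arviz as az

        return az.from_dict(posterior=self.posterior, sample_stats=self.sample_stats)


def sample_posterior(model, config: SamplerConfig) -> PosteriorDraws:
    """Run NUTS chains for ``model`` and return constrained draws."""
    space = model.space
    opts = NUTSOptions(
        max_treedepth=config.max_treedepth, target_accept=config.target_accept
    )
    z_init = space.pack(model.initial_params())
    lp0, _ = model.logp_grad(z_init)
    if not np.isfinite(lp0):
        raise RuntimeError("initial point has non-finite log density")

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    n_post = config.n_iterations - config.n_warmup
    all_draws = []
    all_stats = []
    for c in range(config.n_chains):
        rng = np.random.default_rng(seeds[c])
        z0 = None
        for scale in (0.1, 0.01, 0.0):
            cand = z_init + scale * rng.standard_normal(space.dim)
            lp, _ = model.logp_grad(cand)
            if np.isfinite(lp):
                z0 = cand
                break
        if z0 is None:
            raise RuntimeError(
                f"chain {c}: could not find a finite initial point near the "
                "data-informed start"
            )
        draws, stats = nuts_chain(
            model.logp_grad, z0, config.n_warmup, n_post, rng, opts
        )
        keep = slice(0, n_post, config.thin)
        all_draws.append(draws[keep])
        all_stats.append({k: v[keep] for k, v in stats.items()})

    z = np.stack(all_draws)  # (chain, draw, dim)
    posterior: dict[str, np.ndarray] = {}
    for b in space.blocks:
        sl = space._slices[b.name]
        zz = z[:, :, sl]
        if b.transform == "log":
            x = np.exp(zz)
        elif b.transform == "interval":
            from scipy.special import expit

            x = b.lo + (b.hi - b.lo) * expit(zz)
        elif b.transform == "scale":
            x = b.scale * zz
        else:
            x = zz
        posterior[b.name] = x.reshape(z.shape[0], z.shape[1], *b.shape)

    sample_stats = {
        k: np.stack([s[k] for s in all_stats]) for k in all_stats[0]
    }
    return PosteriorDraws(
        posterior=posterior, sample_stats=sample_stats, config=config,
        attrs={"model": type(model).__name__, "dim": space.dim},
    )
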