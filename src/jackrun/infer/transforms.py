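"""Unconstrained reparameterization of model parameter blocks.

HMC runs on an unconstrained vector ``z``; each named block maps to its
constrained support through an elementwise transform (identity, exp for
positive scales, scaled logit for interval-bounded parameters), with the log
Jacobian added to the target density and gradients chained accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log, prod

import numpy as np
from scipy.special import expit, logit

__all__ = ["Block", "ParameterSpace"]


@dataclass(frozen=True)
class Block:
    name: str
    shape: tuple[int, ...]
    transform: str = "identity"  # identity | log | interval | scale
    lo: float = 0.0
    hi: float = 1.0
    scale: float = 1.0  # for "scale": x = scale * z

    @property
    def size(self) -> int:
        return int(prod(self.shape)) if self.shape else 1


class ParameterSpace:
    """Ordered collection of blocks defining pack/unpack and Jacobians."""

    def __init__(self, blocks: list[Block]):
        self.blocks = blocks
        self.dim = sum(b.size for b in blocks)
        self._slices: dict[str, slice] = {}
        off = 0
        for b in blocks:
            self._slices[b.name] = slice(off, off + b.size)
            off += b.size

    def pack(self, params: dict[str, np.ndarray]) -> np.ndarray:
        """Constrained dict -> unconstrained vector."""
        z = np.empty(self.dim)
        for b in self.blocks:
            x = np.asarray(params[b.name], dtype=float).reshape(-1)
            if b.transform == "identity":
                z[self._slices[b.name]] = x
            elif b.transform == "log":
                z[self._slices[b.name]] = np.log(x)
            elif b.transform == "interval":
                z[self._slices[b.name]] = logit((x - b.lo) / (b.hi - b.lo))
            elif b.transform == "scale":
                z[self._slices[b.name]] = x / b.scale
            else:  # pragma: no cover
                raise ValueError(b.transform)
        return z

    def unpack(self, z: np.ndarray) -> dict[str, np.ndarray]:
        """Unconstrained vector -> constrained dict (no Jacobian)."""
        out = {}
        for b in self.blocks:
            zz = z[self._slices[b.name]].reshape(b.shape)
            if b.transform == "identity":
                x = zz.copy()
            elif b.transform == "log":
                x = np.exp(zz)
            elif b.transform == "scale":
                x = b.scale * zz
            else:
                x = b.lo + (b.hi - b.lo) * expit(zz)
            out[b.name] = x if b.shape else float(x)
        return out

    def log_jacobian(self, z: np.ndarray) -> float:
        lj = 0.0
        for b in self.blocks:
            zz = z[self._slices[b.name]]
            if b.transform == "log":
                lj += float(zz.sum())
            elif b.transform == "interval":
                s = expit(zz)
                lj += float(np.sum(np.log(b.hi - b.lo) + np.log(s) + np.log1p(-s)))
            elif b.transform == "scale":
                lj += len(zz) * log(b.scale)
        return lj

    def chain_grad(
        self, z: np.ndarray, grads: dict[str, np.ndarray]
    ) -> np.ndarray:
        """Map d(logp)/d(constrained) to d(logp + logJac)/dz."""
        gz = np.zeros(self.dim)
        for b in self.blocks:
            sl = self._slices[b.name]
            zz = z[sl]
            gx = np.asarray(grads[b.name], dtype=float).reshape(-1)
            if b.transform == "identity":
                gz[sl] = gx
            elif b.transform == "log":
                gz[sl] = gx * np.exp(zz) + 1.0
            elif b.transform == "scale":
                gz[sl] = gx * b.scale
            else:
                s = expit(zz)
                gz[sl] = gx * (b.hi - b.lo) * s * (1.0 - s) + (1.0 - 2.0 * s)
        return gz
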