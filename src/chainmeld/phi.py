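"""Layout of the concatenated shared-quantity vector phi.

A chain of ``M`` submodels has ``M - 1`` overlaps: submodels ``m`` and
``m + 1`` share the quantity ``phi_{m ∩ m+1}``.  The full shared vector is
the concatenation ``phi = (phi_{1∩2}, ..., phi_{M-1∩M})``.  A
:class:`PhiLayout` fixes the order, names and dimensions of these blocks
once, so that every density evaluator, pooling operator and sampler agrees
on the coordinates without positional conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import LayoutError

__all__ = ["PhiLayout"]


@dataclass(frozen=True)
class PhiLayout:
    """Named, ordered blocks of the concatenated shared vector.

    Parameters
    ----------
    names
        Overlap names in chain order, e.g. ``("phi12", "phi23")``.
        Entry ``m`` (0-based) names the quantity shared by submodels
        ``m + 1`` and ``m + 2`` (1-based chain positions).
    dims
        Dimension of each block (all >= 1).
    """

    names: tuple[str, ...]
    dims: tuple[int, ...]
    _offsets: tuple[int, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.dims):
            raise LayoutError("names and dims must have equal length")
        if len(self.names) == 0:
            raise LayoutError("a chain needs at least one overlap")
        if len(set(self.names)) != len(self.names):
            raise LayoutError(f"duplicate overlap names in {self.names}")
        if any(d < 1 for d in self.dims):
            raise LayoutError(f"all block dimensions must be >= 1, got {self.dims}")
        offsets = tuple(int(x) for x in np.concatenate([[0], np.cumsum(self.dims)[:-1]]))
        object.__setattr__(self, "_offsets", offsets)

    @property
    def n_overlaps(self) -> int:
        return len(self.names)

    @property
    def total_dim(self) -> int:
        return int(sum(self.dims))

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise LayoutError(f"unknown overlap {name!r}; layout has {self.names}") from None

    def slice_of(self, name: str) -> slice:
        i = self.index(name)
        return slice(self._offsets[i], self._offsets[i] + self.dims[i])

    def extract(self, phi: np.ndarray, names: tuple[str, ...]) -> np.ndarray:
        """Subvector of ``phi`` covering ``names`` (in layout order given)."""
        phi = np.asarray(phi, dtype=float)
        if phi.shape[-1] != self.total_dim:
            raise LayoutError(
                f"phi has trailing dimension {phi.shape[-1]}, layout expects {self.total_dim}"
            )
        parts = [phi[..., self.slice_of(n)] for n in names]
        return np.concatenate(parts, axis=-1)

    def dim_of(self, names: tuple[str, ...]) -> int:
        return int(sum(self.dims[self.index(n)] for n in names))

    def pack(self, **blocks: np.ndarray) -> np.ndarray:
        """Assemble a full phi vector from named blocks."""
        out = np.empty(self.total_dim)
        seen = set()
        for name, value in blocks.items():
            sl = self.slice_of(name)
            value = np.atleast_1d(np.asarray(value, dtype=float))
            if value.shape != (self.dims[self.index(name)],):
                raise LayoutError(
                    f"block {name!r} has shape {value.shape}, expected ({self.dims[self.index(name)]},)"
                )
            out[sl] = value
            seen.add(name)
        if seen != set(self.names):
            raise LayoutError(f"pack needs all blocks {self.names}, got {sorted(seen)}")
        return out
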