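"""Shared helpers: exceptions and seed-substream derivation."""

from __future__ import annotations

import numpy as np

# Fixed per-generator stream tags.  A single user-facing integer seed fans out
# to independent substreams via ``np.random.default_rng([tag, seed])``; the tag
# assignment below is part of the public contract and must not be reordered.
STREAM_TAGS = {
    "bold": 101,
    "cohort_fc": 102,
    "spatial": 103,
    "labels": 104,
    "clinical": 105,
    "bootstrap": 201,
    "crossval": 202,
    "permutation": 203,
    "split_half": 204,
    "pls_annotation": 301,
}


class DimensionError(ValueError):
    """Array shapes or requested ranks are incompatible."""


class DataError(ValueError):
    """Input values violate a data contract (non-finite, wrong schema...)."""


class GeometryError(ValueError):
    """A requested vector geometry (e.g. Gram matrix) is unrealisable."""


class ParameterError(ValueError):
    """Parameter combination outside the supported regime."""


class DecayFitError(RuntimeError):
    """Nonlinear decay fit failed; carries initialisation and data summary."""


def substream(seed: int, name: str) -> np.random.Generator:
    """Return the named substream of a global integer seed."""
    return np.random.default_rng([STREAM_TAGS[name], int(seed)])


def check_finite(arr: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise DataError(f"{what} contains non-finite values")
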