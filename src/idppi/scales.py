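"""Amino-acid propensity scales and their standardization.

Five scales ship as package data: TOP-IDP (order/disorder propensity),
B-values (flexibility), FoldUnfold (contact-forming capacity), a DisProt
compositional-bias surrogate, and side-chain net charge. Any 2-column
``residue<TAB>value`` file can be loaded as a user scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .sequences import STANDARD_AA

_BUILTIN_FILES = {
    "top-idp": "top_idp.tsv",
    "b-values": "b_values.tsv",
    "fold-unfold": "fold_unfold.tsv",
    "disprot": "disprot_synthetic.tsv",
    "net-charge": "net_charge.tsv",
}

#: Names of the five scales used by the default PAAC configuration.
DEFAULT_PAAC_SCALE_NAMES = tuple(_BUILTIN_FILES)


@dataclass(frozen=True)
class PropensityScale:
    """A named mapping of the 20 standard residues to real numbers."""

    name: str
    values: dict[str, float]
    standardized: bool = field(default=False)

    def __post_init__(self) -> None:
        keys = set(self.values)
        if keys != set(STANDARD_AA):
            missing = sorted(set(STANDARD_AA) - keys)
            extra = sorted(keys - set(STANDARD_AA))
            raise ConfigurationError(
                f"scale {self.name!r}: must map exactly the 20 standard residues"
                + (f"; missing {missing}" if missing else "")
                + (f"; unexpected {extra}" if extra else "")
            )

    def as_array(self) -> np.ndarray:
        """Values ordered alphabetically by one-letter code."""
        return np.array([self.values[aa] for aa in STANDARD_AA], dtype=float)

    def standardize(self) -> "PropensityScale":
        """Return a zero-mean, unit-variance copy (population convention, n=20).

        Idempotent: standardizing a standardized scale changes nothing
        beyond floating-point round-off.
        """
        arr = self.as_array()
        sd = arr.std()  # ddof=0
        if sd == 0:
            raise ConfigurationError(f"scale {self.name!r}: constant values cannot be standardized")
        arr = (arr - arr.mean()) / sd
        return PropensityScale(
            name=self.name,
            values=dict(zip(STANDARD_AA, arr.tolist())),
            standardized=True,
        )


def load_scale(path, name: str | None = None) -> PropensityScale:
    """Load a 2-column delimited scale file; '#' lines are comments."""
    path = Path(path)
    values: dict[str, float] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", "\t").split()
        if len(parts) != 2:
            raise ConfigurationError(f"{path}:{lineno}: expected 'residue value', got {line!r}")
        residue, value = parts
        residue = residue.upper()
        if residue in values:
            raise ConfigurationError(f"{path}:{lineno}: duplicate residue {residue!r}")
        values[residue] = float(value)
    return PropensityScale(name=name or path.stem, values=values)


def builtin_scale(name: str) -> PropensityScale:
    """Load one of the packaged scales by name (see DEFAULT_PAAC_SCALE_NAMES)."""
    try:
        fname = _BUILTIN_FILES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown built-in scale {name!r}; choose from {sorted(_BUILTIN_FILES)}"
        ) from None
    ref = resources.files("idppi").joinpath("data", "scales", fname)
    with resources.as_file(ref) as path:
        return load_scale(path, name=name)


def default_paac_scales() -> list[PropensityScale]:
    """The five packaged scales, in canonical order, unstandardized."""
    return [builtin_scale(n) for n in DEFAULT_PAAC_SCALE_NAMES]
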