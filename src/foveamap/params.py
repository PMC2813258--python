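"""Model parameters for the V1-V2-V3 retino-cortical projection family.

The parameter set is shared by every map variant:

``k``
    overall cortical scale in mm; the only parameter carrying mm units.
``a``
    foveal pole in degrees: eccentricity scale at which foveal
    magnification saturates (limit of the foveal singularity).
``b``
    peripheral pole in degrees: controls the tapering of the map towards
    the far periphery (dipole variants only).
``lam``
    banding shift in degrees of intermediate ("pacman") space; ``lam > 0``
    turns the foveal apex of V2/V3 into a line, producing the banded
    foveal confluence.
``alpha1..alpha3``
    angular compression of V1, V2 and V3 in the intermediate space
    (dimensionless, ``0 < alpha3 <= alpha2 <= alpha1 <= 1``).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import yaml

#: canonical variant names
VARIANTS = ("monopole", "dipole", "sheared_monopole", "sheared_dipole")

#: accepted aliases -- the sheared variants are known in the retinotopy
#: literature as the (banded) double-sech model family.
_VARIANT_ALIASES = {
    "double_sech_monopole": "sheared_monopole",
    "double_sech_dipole": "sheared_dipole",
    "double-sech-monopole": "sheared_monopole",
    "double-sech-dipole": "sheared_dipole",
}


def canonical_variant(name: str) -> str:
    """Resolve a variant name or alias to its canonical form."""
    name = name.strip().lower()
    name = _VARIANT_ALIASES.get(name, name)
    if name not in VARIANTS:
        raise ValueError(
            f"unknown map variant {name!r}; expected one of {VARIANTS} "
            f"or aliases {tuple(_VARIANT_ALIASES)}"
        )
    return name


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the retino-cortical map family.

    Defaults are the canonical human values: ``a = 1.05`` deg,
    ``b = 90`` deg, ``lam = 0.4``, ``k = 20`` mm, V1:V2:V3 angular
    compression 1 : 0.5 : 0.4.
    """

    k: float = 20.0
    a: float = 1.05
    b: float = 90.0
    lam: float = 0.4
    alpha1: float = 1.0
    alpha2: float = 0.5
    alpha3: float = 0.4
    variant: str = field(default="sheared_dipole")

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant", canonical_variant(self.variant))
        if not self.k > 0:
            raise ValueError(f"k must be > 0, got {self.k}")
        if not 0 < self.a < self.b:
            raise ValueError(f"need 0 < a < b, got a={self.a}, b={self.b}")
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if not 0 < self.alpha3 <= self.alpha2 <= self.alpha1 <= 1:
            raise ValueError(
                "need 0 < alpha3 <= alpha2 <= alpha1 <= 1, got "
                f"{self.alpha1}, {self.alpha2}, {self.alpha3}"
            )

    # -- derived geometry ------------------------------------------------
    @property
    def is_dipole(self) -> bool:
        return self.variant in ("dipole", "sheared_dipole")

    @property
    def is_sheared(self) -> bool:
        return self.variant in ("sheared_monopole", "sheared_dipole")

    @property
    def alphas(self) -> tuple[float, float, float]:
        return (self.alpha1, self.alpha2, self.alpha3)

    @property
    def pacman_span(self) -> float:
        """Half angular span of the intermediate space, radians."""
        import math

        return math.pi / 2 * (self.alpha1 + self.alpha2 + self.alpha3)

    def with_(self, **updates) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **updates)

    # -- serialization ---------------------------------------------------
    _KEY_MAP = {
        "k": "k", "a_deg": "a", "b_deg": "b", "lambda_deg": "lam",
        "alpha1": "alpha1", "alpha2": "alpha2", "alpha3": "alpha3",
        "variant": "variant",
    }

    def to_dict(self) -> dict:
        return {
            "k": self.k, "a_deg": self.a, "b_deg": self.b,
            "lambda_deg": self.lam, "alpha1": self.alpha1,
            "alpha2": self.alpha2, "alpha3": self.alpha3,
            "variant": self.variant,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelParams":
        kwargs = {}
        for key, val in d.items():
            if key in cls._KEY_MAP:
                kwargs[cls._KEY_MAP[key]] = val
            elif key in ("a", "b", "lam", "lambda"):
                kwargs[{"lambda": "lam"}.get(key, key)] = val
            else:
                raise ValueError(f"unknown parameter key {key!r}")
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(d, sort_keys=False))
        else:
            path.write_text(json.dumps(d, indent=2))

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParams":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


#: names of the scalar parameters that may be freed in fitting
FITTABLE = ("k", "a", "b", "lam")

#: hard parameter bounds used by the estimators (k mm, a/b/lam deg)
DEFAULT_BOUNDS: Mapping[str, tuple[float, float]] = {
    "k": (5.0, 50.0),
    "a": (1e-3, 5.0),
    "b": (40.0, 180.0),
    "lam": (0.0, 2.0),
}


def validate_free(free: Iterable[str]) -> tuple[str, ...]:
    free = tuple(free)
    for name in free:
        if name not in FITTABLE:
            raise ValueError(f"cannot free parameter {name!r}; fittable: {FITTABLE}")
    return free
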