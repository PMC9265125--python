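"""Feature registry: the single source of truth for names and counts."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml

#: contractual per-family feature counts
EXPECTED_COUNTS = {
    "MORPH": 8,
    "INT": 18,
    "HIST": 20,
    "GLCM": 11,
    "GLRLM": 13,
    "GLSZM": 13,
    "NGLDM": 16,
    "NGTDM": 5,
}

TEXTURE_FAMILIES = ("GLCM", "GLRLM", "GLSZM", "NGLDM", "NGTDM")


class RegistryError(RuntimeError):
    """The shipped registry violates the contractual feature counts."""


@lru_cache(maxsize=1)
def load_registry() -> dict:
    """Load and validate the shipped feature registry."""
    text = (
        resources.files("sbradiomics") / "data" / "feature_registry.yaml"
    ).read_text()
    reg = yaml.safe_load(text)
    families = reg["families"]
    for fam, expected in EXPECTED_COUNTS.items():
        names = families.get(fam, [])
        if len(names) != expected:
            raise RegistryError(
                f"registry family {fam} has {len(names)} features, expected {expected}"
            )
        if len(set(names)) != len(names):
            raise RegistryError(f"registry family {fam} has duplicate names")
    return reg


def family_features(family: str) -> tuple[str, ...]:
    """Ordered feature names of one family."""
    return tuple(load_registry()["families"][family])


def registry_version() -> int:
    return int(load_registry()["registry_version"])
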