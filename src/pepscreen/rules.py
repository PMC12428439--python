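"""Drug-likeness rule sets as data, and deterministic violation counting.

Three built-in rule sets are provided:

* ``ro5`` — Lipinski's Rule of Five: Mw <= 500 Da, logP in [0, 5] (the lower
  bound is togglable and on by default), HBD <= 5, HBA <= 10.
* ``bro5`` — the beyond-Rule-of-Five extension for peptide space:
  Mw <= 1000 Da, logP in [-2, 10], HBD <= 6, HBA <= 15, TPSA <= 250 A^2,
  rotatable bonds <= 20.
* ``muegge`` — the Muegge pharmacophore-point filter. The default ``core6``
  variant keeps only the six property bounds (Mw in [200, 600], logP in
  [-2, 5], TPSA <= 150, rotatable bonds <= 15, HBA <= 10, HBD <= 5); the
  ``full`` variant adds the topological / composition criteria
  (rings <= 7, carbons > 4, heteroatoms > 1).

Bounds are inclusive for compliance: a descriptor sitting exactly on its
bound does not violate the criterion. The violation count of a molecule is
simply the number of failed criteria.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MissingDescriptorError
from .molecules import DESCRIPTOR_KEYS, DescriptorVector

RULE_NAMES = ("ro5", "bro5", "muegge")


@dataclass(frozen=True)
class RuleCriterion:
    """One interval criterion over a descriptor key.

    A value complies iff ``lower <= value <= upper`` for whichever bounds are
    set; violation is the strict complement.
    """

    descriptor_key: str
    lower: float | None = None
    upper: float | None = None
    label: str = ""

    def __post_init__(self):
        if self.descriptor_key not in DESCRIPTOR_KEYS:
            raise ConfigurationError(f"unknown descriptor key {self.descriptor_key!r}")
        if self.lower is None and self.upper is None:
            raise ConfigurationError(f"criterion {self.label!r} has no bounds")
        if self.lower is not None and self.upper is not None and self.lower > self.upper:
            raise ConfigurationError(f"criterion {self.label!r}: lower > upper")

    def violated(self, value: float) -> bool:
        if self.lower is not None and value < self.lower:
            return True
        if self.upper is not None and value > self.upper:
            return True
        return False


@dataclass(frozen=True)
class RuleSet:
    """A named, ordered list of interval criteria."""

    name: str
    variant: str
    criteria: tuple[RuleCriterion, ...]

    def __post_init__(self):
        if not self.criteria:
            raise ConfigurationError("rule set has no criteria")

    @property
    def max_violations(self) -> int:
        return len(self.criteria)

    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "variant": self.variant,
            "criteria": [
                {
                    "descriptor_key": c.descriptor_key,
                    "lower": c.lower,
                    "upper": c.upper,
                    "label": c.label,
                }
                for c in self.criteria
            ],
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RuleSet":
        payload = json.loads(text)
        return cls(
            name=payload["name"],
            variant=payload.get("variant", "custom"),
            criteria=tuple(RuleCriterion(**c) for c in payload["criteria"]),
        )

    def thresholds_fingerprint(self) -> str:
        """Stable short hash of the serialized thresholds, embedded in model
        metadata so a model can never be silently applied against labels
        produced by different thresholds."""
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass(frozen=True)
class ViolationResult:
    count: int
    flags: tuple[bool, ...]


def builtin_ruleset(
    name: str,
    *,
    variant: str | None = None,
    logp_lower: bool = True,
) -> RuleSet:
    """Return one of the canonical rule sets.

    ``logp_lower`` toggles the Ro5 logP >= 0 criterion bound (on by default;
    turning it off reproduces the SwissADME/Molinspiration convention where
    only logP > 5 counts). ``variant`` selects ``core6`` (default) or
    ``full`` for Muegge.
    """
    if name == "ro5":
        return RuleSet(
            name="ro5",
            variant="lower-on" if logp_lower else "lower-off",
            criteria=(
                RuleCriterion("mw", upper=500, label="Mw <= 500"),
                RuleCriterion(
                    "logp",
                    lower=0 if logp_lower else None,
                    upper=5,
                    label="logP in [0, 5]" if logp_lower else "logP <= 5",
                ),
                RuleCriterion("hbd", upper=5, label="HBD <= 5"),
                RuleCriterion("hba", upper=10, label="HBA <= 10"),
            ),
        )
    if name == "bro5":
        return RuleSet(
            name="bro5",
            variant="standard",
            criteria=(
                RuleCriterion("mw", upper=1000, label="Mw <= 1000"),
                RuleCriterion("logp", lower=-2, upper=10, label="cLogP in [-2, 10]"),
                RuleCriterion("hbd", upper=6, label="HBD <= 6"),
                RuleCriterion("hba", upper=15, label="HBA <= 15"),
                RuleCriterion("tpsa", upper=250, label="PSA <= 250"),
                RuleCriterion("n_rotb", upper=20, label="NRotB <= 20"),
            ),
        )
    if name == "muegge":
        variant = variant or "core6"
        core = (
            RuleCriterion("mw", lower=200, upper=600, label="Mw in [200, 600]"),
            RuleCriterion("logp", lower=-2, upper=5, label="logP in [-2, 5]"),
            RuleCriterion("tpsa", upper=150, label="TPSA <= 150"),
            RuleCriterion("n_rotb", upper=15, label="NRotB <= 15"),
            RuleCriterion("hba", upper=10, label="HBA <= 10"),
            RuleCriterion("hbd", upper=5, label="HBD <= 5"),
        )
        if variant == "core6":
            return RuleSet(name="muegge", variant="core6", criteria=core)
        if variant == "full":
            return RuleSet(
                name="muegge",
                variant="full",
                criteria=core
                + (
                    RuleCriterion("n_rings", upper=7, label="rings <= 7"),
                    RuleCriterion("n_carbon", lower=5, label="carbons > 4"),
                    RuleCriterion("n_hetero", lower=2, label="heteroatoms > 1"),
                ),
            )
        raise ConfigurationError(f"unknown muegge variant {variant!r}")
    raise ConfigurationError(f"unknown rule set {name!r} (expected one of {RULE_NAMES})")


def count_violations(dv: DescriptorVector | Mapping[str, float], rs: RuleSet) -> ViolationResult:
    """Count how many of ``rs``'s criteria ``dv`` fails.

    Pure function of its inputs. Raises :class:`MissingDescriptorError` if a
    referenced descriptor is absent (mapping inputs only; a DescriptorVector
    is always fully populated).
    """
    values = dv.as_dict() if isinstance(dv, DescriptorVector) else dv
    flags = []
    for c in rs.criteria:
        if c.descriptor_key not in values or values[c.descriptor_key] is None:
            raise MissingDescriptorError(
                f"descriptor {c.descriptor_key!r} required by rule {rs.name!r} is missing"
            )
        flags.append(c.violated(values[c.descriptor_key]))
    return ViolationResult(count=sum(flags), flags=tuple(flags))


def count_violations_frame(table: pd.DataFrame, rs: RuleSet) -> np.ndarray:
    """Vectorized violation counts for a descriptor table (one row per molecule)."""
    counts = np.zeros(len(table), dtype=np.int64)
    for c in rs.criteria:
        if c.descriptor_key not in table.columns:
            raise MissingDescriptorError(
                f"descriptor column {c.descriptor_key!r} required by rule {rs.name!r} is missing"
            )
        col = table[c.descriptor_key].to_numpy()
        violated = np.zeros(len(table), dtype=bool)
        if c.lower is not None:
            violated |= col < c.lower
        if c.upper is not None:
            violated |= col > c.upper
        counts += violated
    return counts


def max_violations(rs: RuleSet) -> int:
    return rs.max_violations


def ro5_pass(result: ViolationResult | int) -> bool:
    """Lipinski's classical heuristic: at most one violation. Derived
    convenience only — never a training target."""
    count = result.count if isinstance(result, ViolationResult) else int(result)
    return count <= 1
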