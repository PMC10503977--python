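"""Rule-based drug-likeness filters and the Abbott bioavailability score.

Implements the five classical oral-bioavailability rule sets on supplied
physicochemical properties (properties are *inputs*, not computed from
structures):

* **Lipinski** rule of five — MW ≤ 500 Da, LogP ≤ 5, HBA ≤ 10, HBD ≤ 5;
  one violation is tolerated.
* **Veber** — rotatable bonds ≤ 10, TPSA ≤ 140 Å².
* **Egan** — WLOGP ≤ 5.88, TPSA ≤ 131.6 Å².
* **Muegge** — 200 ≤ MW ≤ 600, −2 ≤ XLOGP ≤ 5, TPSA ≤ 150, rings ≤ 7,
  carbons > 4, heteroatoms > 1, rotatable bonds ≤ 15, HBA ≤ 10, HBD ≤ 5.
* **Ghose** — 160 ≤ MW ≤ 480, −0.4 ≤ WLOGP ≤ 5.6, 40 ≤ MR ≤ 130,
  20 ≤ atoms ≤ 70.

A condition whose input property is absent is reported "not evaluable" and
excluded from the violation count.  Property keys: ``MW`` (Da), ``LogP``,
``WLOGP``, ``XLOGP``, ``HBA``, ``HBD``, ``TPSA`` (Å²), ``RotB``, ``MR``,
``Atoms``, ``Rings``, ``Carbons``, ``Heteroatoms``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

__all__ = ["RuleResult", "RuleReport", "evaluate_rules", "bioavailability_score"]


@dataclass
class RuleResult:
    """One rule set's verdict on one compound."""

    name: str
    passed: bool
    violations: list[str] = field(default_factory=list)
    not_evaluable: list[str] = field(default_factory=list)
    allowed_violations: int = 0

    @property
    def violation_count(self) -> int:
        return len(self.violations)


@dataclass
class RuleReport:
    """All rule verdicts for one compound, plus the bioavailability score."""

    rules: dict[str, RuleResult]
    bioavailability_score: float | None = None

    def __getitem__(self, name: str) -> RuleResult:
        return self.rules[name]


# (label, property key, lower bound, upper bound); bounds inclusive, None = open
_RULES: dict[str, tuple[int, list[tuple[str, str, float | None, float | None]]]] = {
    "lipinski": (
        1,
        [
            ("MW>500", "MW", None, 500.0),
            ("LogP>5", "LogP", None, 5.0),
            ("HBA>10", "HBA", None, 10.0),
            ("HBD>5", "HBD", None, 5.0),
        ],
    ),
    "veber": (
        0,
        [
            ("RotB>10", "RotB", None, 10.0),
            ("TPSA>140", "TPSA", None, 140.0),
        ],
    ),
    "egan": (
        0,
        [
            ("WLOGP>5.88", "WLOGP", None, 5.88),
            ("TPSA>131.6", "TPSA", None, 131.6),
        ],
    ),
    "muegge": (
        0,
        [
            ("MW<200", "MW", 200.0, None),
            ("MW>600", "MW", None, 600.0),
            ("XLOGP<-2", "XLOGP", -2.0, None),
            ("XLOGP>5", "XLOGP", None, 5.0),
            ("TPSA>150", "TPSA", None, 150.0),
            ("Rings>7", "Rings", None, 7.0),
            ("Carbons<5", "Carbons", 4.0 + 1e-9, None),  # strict: C > 4
            ("Heteroatoms<2", "Heteroatoms", 1.0 + 1e-9, None),  # strict: > 1
            ("RotB>15", "RotB", None, 15.0),
            ("HBA>10", "HBA", None, 10.0),
            ("HBD>5", "HBD", None, 5.0),
        ],
    ),
    "ghose": (
        0,
        [
            ("MW<160", "MW", 160.0, None),
            ("MW>480", "MW", None, 480.0),
            ("WLOGP<-0.4", "WLOGP", -0.4, None),
            ("WLOGP>5.6", "WLOGP", None, 5.6),
            ("MR<40", "MR", 40.0, None),
            ("MR>130", "MR", None, 130.0),
            ("Atoms<20", "Atoms", 20.0, None),
            ("Atoms>70", "Atoms", None, 70.0),
        ],
    ),
}


def _get(props: Mapping[str, float], key: str) -> float | None:
    val = props.get(key)
    if val is None or (isinstance(val, float) and math.isnan(val)):
        return None
    return float(val)


def evaluate_rules(props: Mapping[str, float]) -> RuleReport:
    """Evaluate every rule set on one compound's property record.

    A rule passes when its violation count does not exceed its allowance
    (1 for Lipinski, 0 for the rest).  Violated conditions are reported as
    strings in the printed style, e.g. ``"WLOGP>5.6"``; conditions whose
    inputs are absent land in ``not_evaluable`` and do not count.
    """
    mw = _get(props, "MW")
    if mw is not None and mw <= 0:
        raise ValueError(f"non-physical molecular weight {mw}")

    rules: dict[str, RuleResult] = {}
    for rule_name, (allowance, conditions) in _RULES.items():
        violations: list[str] = []
        missing: list[str] = []
        for label, key, lo, hi in conditions:
            val = _get(props, key)
            if val is None:
                missing.append(label)
                continue
            if (lo is not None and val < lo) or (hi is not None and val > hi):
                violations.append(label)
        rules[rule_name] = RuleResult(
            name=rule_name,
            passed=len(violations) <= allowance,
            violations=violations,
            not_evaluable=missing,
            allowed_violations=allowance,
        )

    report = RuleReport(rules=rules)
    try:
        report.bioavailability_score = bioavailability_score(props)
    except ValueError:
        report.bioavailability_score = None
    return report


def _ro5_violations(props: Mapping[str, float]) -> int:
    count = 0
    for _, key, lo, hi in _RULES["lipinski"][1]:
        val = _get(props, key)
        if val is None:
            continue
        if (lo is not None and val < lo) or (hi is not None and val > hi):
            count += 1
    return count


def bioavailability_score(
    props: Mapping[str, float], charge_class: str = "neutral"
) -> float:
    """Abbott (Martin) bioavailability score: P(F > 10% in rat), binned.

    Anions are scored by polar surface area (TPSA ≤ 75 → 0.85;
    75 < TPSA ≤ 150 → 0.56; TPSA > 150 → 0.11).  Everything else is scored
    by rule-of-five compliance: fewer than two violations → 0.55, two or
    more → 0.17.
    """
    if charge_class not in ("neutral", "cation", "anion", "zwitterion"):
        raise ValueError(f"unknown charge class {charge_class!r}")
    if charge_class == "anion":
        tpsa = _get(props, "TPSA")
        if tpsa is None:
            raise ValueError("TPSA required to score an anion")
        if tpsa <= 75:
            return 0.85
        return 0.56 if tpsa <= 150 else 0.11
    return 0.55 if _ro5_violations(props) < 2 else 0.17
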