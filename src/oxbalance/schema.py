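"""Declarative oxidative balance score (OBS) schema, cutpoints and validation.

The OBS sums 0/1/2 points over 20 dietary and lifestyle components.  Each
component carries a *polarity* (antioxidant components earn more points at
higher exposure, prooxidant components the reverse) and a *scoring rule*:
every component except alcohol is cut at sex-specific tertile boundaries,
while alcohol uses fixed heavy-drinking thresholds (30 g/d for men, 15 g/d
for women, nondrinker = exactly 0 g/d).

The default schema and its tertile cutpoints ship as a packaged YAML config
so scoring works with no external downloads; both can be overridden, and
cutpoints may instead be recomputed from data (see
:func:`oxbalance.scoring.compute_cutpoints`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterator, Literal, Mapping

import yaml

__all__ = [
    "ComponentSpec",
    "OBSSchema",
    "CutpointSet",
    "AlcoholRule",
    "SchemaError",
    "load_default_schema",
    "load_default_cutpoints",
    "validate_schema",
]

Group = Literal["dietary", "lifestyle"]
Polarity = Literal["antioxidant", "prooxidant"]
Rule = Literal["sex_tertile", "fixed_alcohol"]
Sex = Literal["male", "female"]

SEXES: tuple[Sex, Sex] = ("male", "female")

PACKAGED_PROVENANCE = "packaged_table1"
COMPUTED_PROVENANCE = "computed_from_data"


class SchemaError(ValueError):
    """A schema, cutpoint table or cohort table violates its contract."""


@dataclass(frozen=True)
class ComponentSpec:
    """One scored OBS component."""

    name: str
    group: Group
    polarity: Polarity
    rule: Rule = "sex_tertile"
    units: str = ""

    def __post_init__(self) -> None:
        if self.group not in ("dietary", "lifestyle"):
            raise SchemaError(f"unknown group {self.group!r} for {self.name!r}")
        if self.polarity not in ("antioxidant", "prooxidant"):
            raise SchemaError(f"unknown polarity {self.polarity!r} for {self.name!r}")
        if self.rule not in ("sex_tertile", "fixed_alcohol"):
            raise SchemaError(f"unknown rule {self.rule!r} for {self.name!r}")


@dataclass(frozen=True)
class AlcoholRule:
    """Fixed alcohol scoring: nondrinker 2, nonheavy 1, heavy 0.

    Heavy drinking means ≥ ``male_threshold`` g/d for men and
    ≥ ``female_threshold`` g/d for women; a nondrinker reports exactly 0 g/d.
    """

    male_threshold: float = 30.0
    female_threshold: float = 15.0

    def __post_init__(self) -> None:
        if self.male_threshold <= 0 or self.female_threshold <= 0:
            raise SchemaError("alcohol thresholds must be strictly positive")

    def threshold(self, sex: Sex) -> float:
        return self.male_threshold if sex == "male" else self.female_threshold

    def points(self, value: float, sex: Sex) -> int:
        if value < 0:
            raise SchemaError(f"alcohol intake must be >= 0, got {value}")
        if value == 0:
            return 2
        return 0 if value >= self.threshold(sex) else 1


@dataclass(frozen=True)
class OBSSchema:
    """Ordered collection of OBS components plus the alcohol rule."""

    components: tuple[ComponentSpec, ...]
    version: str = "custom"
    alcohol_rule: AlcoholRule = field(default_factory=AlcoholRule)

    def __iter__(self) -> Iterator[ComponentSpec]:
        return iter(self.components)

    def __len__(self) -> int:
        return len(self.components)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components)

    @property
    def dietary(self) -> tuple[ComponentSpec, ...]:
        return tuple(c for c in self.components if c.group == "dietary")

    @property
    def lifestyle(self) -> tuple[ComponentSpec, ...]:
        return tuple(c for c in self.components if c.group == "lifestyle")

    @property
    def max_total(self) -> int:
        return 2 * len(self.components)

    def component(self, name: str) -> ComponentSpec:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    def drop(self, name: str) -> "OBSSchema":
        """Schema with one component removed (leave-one-out sensitivity)."""
        if name not in self.names:
            raise KeyError(name)
        return replace(
            self,
            components=tuple(c for c in self.components if c.name != name),
            version=f"{self.version}-minus-{name}",
        )


@dataclass
class CutpointSet:
    """Sex-specific tertile boundaries (t1, t2) per tertile-scored component.

    ``entries`` maps ``(component name, sex)`` to the ascending pair
    ``(t1, t2)``: the 33⅓ and 66⅔ percentile boundaries in component units.
    Prooxidant components store the same ascending boundaries; the point
    reversal happens at scoring time, driven by polarity.
    """

    entries: dict[tuple[str, Sex], tuple[float, float]]
    provenance: str = COMPUTED_PROVENANCE

    def lookup(self, name: str, sex: Sex) -> tuple[float, float]:
        try:
            return self.entries[(name, sex)]
        except KeyError:
            raise SchemaError(
                f"no tertile cutpoints for component {name!r}, sex {sex!r}"
            ) from None

    def __contains__(self, key: tuple[str, Sex]) -> bool:
        return key in self.entries

    def to_frame(self):
        """Tidy tabular export: component, sex, t1, t2."""
        import pandas as pd

        rows = [
            {"component": name, "sex": sex, "t1": t1, "t2": t2}
            for (name, sex), (t1, t2) in self.entries.items()
        ]
        return pd.DataFrame(rows, columns=["component", "sex", "t1", "t2"])


# ---------------------------------------------------------------------------
# packaged defaults
# ---------------------------------------------------------------------------


def _read_packaged_config() -> Mapping:
    text = (resources.files("oxbalance") / "data" / "obs_schema.yaml").read_text()
    return yaml.safe_load(text)


def schema_from_mapping(cfg: Mapping) -> tuple[OBSSchema, CutpointSet]:
    """Parse a schema + cutpoint mapping (the packaged YAML layout)."""
    rule_cfg = cfg.get("alcohol_rule", {})
    alcohol = AlcoholRule(
        male_threshold=float(rule_cfg.get("male_threshold_g_per_day", 30.0)),
        female_threshold=float(rule_cfg.get("female_threshold_g_per_day", 15.0)),
    )
    comps = []
    entries: dict[tuple[str, Sex], tuple[float, float]] = {}
    for item in cfg["components"]:
        spec = ComponentSpec(
            name=item["name"],
            group=item["group"],
            polarity=item["polarity"],
            rule=item.get("rule", "sex_tertile"),
            units=item.get("units", ""),
        )
        comps.append(spec)
        if spec.rule == "sex_tertile":
            for sex in SEXES:
                t1, t2 = item["cutpoints"][sex]
                entries[(spec.name, sex)] = (float(t1), float(t2))
    schema = OBSSchema(
        components=tuple(comps),
        version=str(cfg.get("version", "custom")),
        alcohol_rule=alcohol,
    )
    cutpoints = CutpointSet(entries=entries, provenance=PACKAGED_PROVENANCE)
    return schema, cutpoints


def schema_to_mapping(schema: OBSSchema, cutpoints: CutpointSet | None = None) -> dict:
    """Inverse of :func:`schema_from_mapping`; round-trips exactly."""
    out: dict = {
        "version": schema.version,
        "alcohol_rule": {
            "male_threshold_g_per_day": schema.alcohol_rule.male_threshold,
            "female_threshold_g_per_day": schema.alcohol_rule.female_threshold,
        },
        "components": [],
    }
    for c in schema:
        item: dict = {
            "name": c.name,
            "group": c.group,
            "polarity": c.polarity,
            "rule": c.rule,
            "units": c.units,
        }
        if c.rule == "sex_tertile" and cutpoints is not None:
            item["cutpoints"] = {
                sex: list(cutpoints.lookup(c.name, sex)) for sex in SEXES
            }
        out["components"].append(item)
    return out


def load_default_schema() -> OBSSchema:
    """The packaged 20-component scheme (16 dietary + 4 lifestyle)."""
    schema, _ = schema_from_mapping(_read_packaged_config())
    return schema


def load_default_cutpoints() -> CutpointSet:
    """Packaged sex-specific tertile boundaries for the default scheme."""
    _, cutpoints = schema_from_mapping(_read_packaged_config())
    return cutpoints


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate_schema(
    schema: OBSSchema, cutpoints: CutpointSet | None = None
) -> list[str]:
    """Collect invariant violations; empty list means valid.

    Checks: unique names; exactly one fixed-rule alcohol component with
    prooxidant polarity in the lifestyle group; ascending (t1 < t2) cutpoints
    covering every tertile component for both sexes; positive alcohol
    thresholds with the male threshold at least the female one.
    """
    violations: list[str] = []
    names = [c.name for c in schema]
    dupes = sorted({n for n in names if names.count(n) > 1})
    for n in dupes:
        violations.append(f"duplicate component name: {n}")

    fixed = [c for c in schema if c.rule == "fixed_alcohol"]
    if len(fixed) != 1:
        violations.append(
            f"expected exactly one fixed_alcohol component, found {len(fixed)}"
        )
    for c in fixed:
        if c.polarity != "prooxidant" or c.group != "lifestyle":
            violations.append(
                f"fixed_alcohol component {c.name!r} must be a lifestyle prooxidant"
            )
    if schema.alcohol_rule.male_threshold < schema.alcohol_rule.female_threshold:
        violations.append("male alcohol threshold below female threshold")

    if cutpoints is not None:
        for c in schema:
            if c.rule != "sex_tertile":
                continue
            for sex in SEXES:
                if (c.name, sex) not in cutpoints:
                    violations.append(f"missing cutpoints for ({c.name}, {sex})")
                    continue
                t1, t2 = cutpoints.lookup(c.name, sex)
                if not t1 < t2:
                    violations.append(
                        f"cutpoints not strictly ascending for ({c.name}, {sex}): "
                        f"t1={t1}, t2={t2}"
                    )
    return violations
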