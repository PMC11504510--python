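"""Configurable NPPM threshold tables.

Every threshold the engines evaluate lives here, per subcategory, so that a
changed NPPM edition (or a corrected value) is a config edit, never a code
change.  Optional thresholds that a subcategory does not define mean the
corresponding check is *not applicable* — never silently zero.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import RulesetError
from .model import ProductGroup

_DEFAULT_PATH = Path(__file__).parent / "data" / "nppm_default.yaml"


class SubcategoryRules(BaseModel):
    """Part A thresholds and Part B applicability for one NPPM subcategory."""

    model_config = ConfigDict(extra="forbid")

    name: str
    group: ProductGroup
    #: confectionery is not a permitted category for this age group
    category_permitted: bool = True
    energy_density_min_kcal_per_100g: Optional[float] = Field(default=None, ge=0)
    energy_max_kcal_per_serve: Optional[float] = Field(default=None, ge=0)
    sodium_max_mg_per_100kcal: Optional[float] = Field(default=None, ge=0)
    sodium_max_mg_per_100kcal_cheese: Optional[float] = Field(default=None, ge=0)
    sugar_max_pct_energy: Optional[float] = Field(default=None, ge=0)
    sugar_flag_threshold_pct_energy: Optional[float] = Field(default=None, ge=0)
    added_water_max_pct: Optional[float] = Field(default=None, ge=0)
    fruit_required_pct: Optional[float] = Field(default=None, ge=0, le=100)
    fruit_declaration_required: bool = False
    protein_min_g_per_100kcal: Optional[float] = Field(default=None, ge=0)
    protein_min_pct_weight: Optional[float] = Field(default=None, ge=0)
    fat_max_g_per_100kcal: Optional[float] = Field(default=None, ge=0)
    added_sugar_prohibited: bool = False
    trans_fat_prohibited: bool = False

    @model_validator(mode="after")
    def _cheese_limit_not_below_base(self) -> "SubcategoryRules":
        if (
            self.sodium_max_mg_per_100kcal is not None
            and self.sodium_max_mg_per_100kcal_cheese is not None
            and self.sodium_max_mg_per_100kcal_cheese < self.sodium_max_mg_per_100kcal
        ):
            raise ValueError("cheese sodium limit must be >= base sodium limit")
        return self


class RuleSet(BaseModel):
    """Full NPPM configuration: taxonomy plus per-subcategory thresholds."""

    model_config = ConfigDict(extra="forbid")

    sugar_energy_factor_kcal_per_g: float = Field(default=4.0, gt=0)
    kj_per_kcal: float = Field(default=4.184, gt=0)
    subcategories: dict[str, SubcategoryRules]

    @property
    def taxonomy(self) -> dict[str, str]:
        """Mapping subcategory code -> product group."""
        return {code: sub.group for code, sub in self.subcategories.items()}

    def rules_for(self, subcategory: str) -> SubcategoryRules:
        try:
            return self.subcategories[subcategory]
        except KeyError:
            raise RulesetError(f"unknown subcategory code: {subcategory!r}") from None

    def codes_in_group(self, group: str) -> list[str]:
        return [code for code, sub in self.subcategories.items() if sub.group == group]


def load_ruleset(path: str | Path) -> RuleSet:
    """Load and validate a YAML/JSON ruleset config."""
    path = Path(path)
    try:
        payload = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise RulesetError(f"cannot parse ruleset config {path}: {exc}") from exc
    try:
        return RuleSet.model_validate(payload)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise RulesetError(f"invalid ruleset config {path}: {loc}: {first['msg']}") from exc


def save_ruleset(rules: RuleSet, path: str | Path) -> None:
    """Write a ruleset config; load_ruleset(save_ruleset(rs)) == rs."""
    payload = rules.model_dump(exclude_none=True)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def default_ruleset() -> RuleSet:
    """The shipped default NPPM configuration (deterministic across runs).

    Thresholds printed in the published evaluation (sodium 50/100 mg/100 kcal,
    sugar 15 % energy, snacks 50 kcal/serve, added water 25 %, fruit 100 %) are
    authoritative; values the evaluation does not print (minimum energy
    densities, protein minima, fat maxima, high-sugar-flag thresholds) are
    documented placeholders in ``nppm_default.yaml`` to be verified against the
    NPPM publication.
    """
    return load_ruleset(_DEFAULT_PATH)
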