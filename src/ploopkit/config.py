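"""Pipeline configuration: component-code lists and geometric cutoffs.

Every threshold used by the pipeline lives here with its default, so a
single config object documents the whole decision surface:

===================  =======  ==================================================
cutoff               default  meaning
===================  =======  ==================================================
lys_beta_max         5.0 Å    Walker-A Lys NZ to nearest β-phosphate O
k1_mg_max            2.5 Å    [Ser/Thr]K+1 hydroxyl O to Mg²⁺ (site-integrity QC)
mg_wb_max            6.0 Å    Mg²⁺ to nearest Walker-B carboxylate O (QC)
wb_search_max        5.0 Å    Walker-B candidate search radius from the K+1 hydroxyl
shell_max            2.6 Å    Mg²⁺ first-shell membership (Mg–O/N)
mimic_assoc_max      3.5 Å    mimic central atom (Al/Be/Mg/V/P) to O3B
wcat_angle_min       140°     minimum O3B–X–Ow angle for the apical water
wcat_dist_range      2–4 Å    Ow distance window from the γ central atom
polar_contact_max    3.6 Å    polar-atom inventory radius around W_cat / γ-moiety
ion_anchor_max       3.0 Å    cofactor ion to the O2B / O1G anchors
===================  =======  ==================================================

Distance cutoffs follow the source survey's printed values where it states
them (5, 2.5, 6, 5, 3.6 Å); the remaining cutoffs are standard
coordination-chemistry scales and are equally overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import yaml


def _default_components() -> dict[str, list[str]]:
    text = resources.files("ploopkit").joinpath("data/components.yaml").read_text()
    return yaml.safe_load(text)["components"]


@dataclass(frozen=True)
class PipelineConfig:
    components: dict[str, list[str]] = field(default_factory=_default_components)
    lys_beta_max: float = 5.0
    k1_mg_max: float = 2.5
    mg_wb_max: float = 6.0
    wb_search_max: float = 5.0
    shell_max: float = 2.6
    mimic_assoc_max: float = 3.5
    wcat_angle_min: float = 140.0
    wcat_dist_min: float = 2.0
    wcat_dist_max: float = 4.0
    polar_contact_max: float = 3.6
    ion_anchor_max: float = 3.0
    hbond_moderate_max: float = 3.2
    resolution_max: float | None = 2.5

    def __post_init__(self) -> None:
        for name in (
            "lys_beta_max", "k1_mg_max", "mg_wb_max", "wb_search_max",
            "shell_max", "mimic_assoc_max", "wcat_angle_min", "wcat_dist_min",
            "wcat_dist_max", "polar_contact_max", "ion_anchor_max",
            "hbond_moderate_max",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"cutoff {name} must be positive")

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load overrides from a YAML file; unspecified fields keep defaults."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        components = data.pop("components", None)
        cfg = cls(**data) if data else cls()
        if components:
            merged = dict(cfg.components)
            merged.update(components)
            cfg = cfg.with_overrides(components=merged)
        return cfg

    # -- component-role helpers -------------------------------------------
    def codes(self, role: str) -> set[str]:
        return set(self.components.get(role, []))

    @property
    def nucleotide_codes(self) -> set[str]:
        return self.codes("ntp") | self.codes("ndp") | self.codes("non_hydrolyzable")


DEFAULT_CONFIG = PipelineConfig()
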