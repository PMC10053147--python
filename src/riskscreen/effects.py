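"""Planted fitness effects for simulated screens.

An :class:`EffectSpec` assigns a gene a signed log2 fitness effect per
(modality, assay) combination, optionally restricted to a named arm so that
context-dependent biology (e.g. a tumor suppressor that only scores in
MEK-activated xenografts) can be planted without modeling the pathway itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

MODALITIES = ("ko", "i", "a")
ASSAYS = ("2D", "3D", "in_vivo", "olaparib")
TRUE_CLASSES = ("oncogene", "tumor_suppressor", "essential", "neutral", "ddr", "context_dependent")


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth fitness effect of one gene.

    ``effects`` maps (modality, assay) to a log2 fold change in fitness; any
    combination not listed is zero. ``context``, if set, names the sample arm
    in which the effects are active (elsewhere the gene is neutral).
    """

    gene_id: str
    true_class: str = "neutral"
    effects: dict[tuple[str, str], float] = field(default_factory=dict)
    context: str | None = None

    def __post_init__(self) -> None:
        if self.true_class not in TRUE_CLASSES:
            raise ValueError(f"unknown true_class {self.true_class!r}")
        for (modality, assay), lfc in self.effects.items():
            if modality not in MODALITIES or assay not in ASSAYS:
                raise ValueError(f"unknown (modality, assay) key ({modality!r}, {assay!r})")
            if self.true_class == "neutral" and lfc != 0:
                raise ValueError("neutral genes must have zero effect everywhere")
            if self.true_class == "essential" and modality == "a" and lfc != 0:
                raise ValueError("essential genes have no effect under activation")

    def lfc(self, modality: str, assay: str, arm: str = "") -> float:
        """Effect applicable to a sample, honoring the context restriction."""
        if self.context is not None and arm != self.context:
            return 0.0
        return self.effects.get((modality, assay), 0.0)


def effects_for_class(
    gene_id: str,
    true_class: str,
    magnitude: float = 2.0,
    context: str | None = None,
) -> EffectSpec:
    """Canonical effect layout for each planted gene class.

    * ``oncogene`` — activation increases fitness in all proliferation assays.
    * ``tumor_suppressor`` — suppression (ko/i) increases fitness in 2D/3D and
      in vivo; activation decreases 2D fitness (the supporting-only signature).
    * ``essential`` — suppression decreases fitness everywhere it grows;
      activation does nothing.
    * ``ddr`` — any perturbation sensitizes to the PARP-inhibitor arm.
    * ``context_dependent`` — suppression helps only in the MEK-activated
      in-vivo arm (pass ``context="mekdd"``).
    * ``neutral`` — no effect.
    """
    m = float(magnitude)
    prolif = ("2D", "3D", "in_vivo")
    if true_class == "oncogene":
        eff = {("a", a): +m for a in prolif}
    elif true_class == "tumor_suppressor":
        eff = {(mod, a): +m for mod in ("ko", "i") for a in prolif}
        eff[("a", "2D")] = -m
    elif true_class == "essential":
        eff = {(mod, a): -abs(m) for mod in ("ko", "i") for a in prolif}
    elif true_class == "ddr":
        eff = {(mod, "olaparib"): -abs(m) for mod in MODALITIES}
    elif true_class == "context_dependent":
        eff = {(mod, "in_vivo"): +m for mod in ("ko", "i")}
        context = context or "mekdd"
    elif true_class == "neutral":
        eff = {}
    else:
        raise ValueError(f"unknown true_class {true_class!r}")
    return EffectSpec(gene_id=gene_id, true_class=true_class, effects=eff, context=context)
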