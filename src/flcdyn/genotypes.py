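"""Genotype presets: named parameter overrides for mutant/transgenic lines.

Presets encode the lines characterized experimentally:

* ``wild_type`` — no overrides (ColFRI-like).
* ``coolair_defective`` — TEX1/TEX2/FLC-delta-COOLAIR-like lines with
  disrupted antisense transcription; the starting nucleated fraction is
  also reduced, reflecting the lower pre-cold H3K27me3 these lines show.
* ``ntl8_D3`` — ectopic antisense in the warm (constitutive slow
  component); nucleation remains cold-gated, because ectopic VIN3 alone
  does not nucleate H3K27me3.
* ``nucleation_mutant`` — vrn2/vin3-like: no nucleation, no pre-switched
  alleles.
* ``spreading_mutant`` — lhp1/clf-like: nucleation intact, no spreading.

Overrides use parameter paths ("k_nuc0", "antisense.disabled", ...) and
are applied to copies; the input parameter objects are never mutated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .params import AntisenseParams, ModelParams, ParamError, get_param, set_param

# factor on wild-type f_N0 for COOLAIR-defective lines (fit-time quantity;
# only the direction — lower than wild type — is constrained by the data)
DEFECTIVE_FN0_FACTOR = 0.4


@dataclass(frozen=True)
class GenotypeSpec:
    """A named set of parameter-path overrides."""

    name: str
    overrides: dict = field(default_factory=dict)

    def with_extra(self, extra: dict) -> "GenotypeSpec":
        merged = dict(self.overrides)
        merged.update(extra)
        return GenotypeSpec(name=self.name, overrides=merged)


def _defective_overrides(params: ModelParams) -> dict:
    return {"antisense.disabled": True,
            "f_N0": DEFECTIVE_FN0_FACTOR * params.f_N0}


def genotype_preset(name: str, params: ModelParams | None = None) -> GenotypeSpec:
    """Resolve a preset name to a GenotypeSpec.

    ``params`` supplies the wild-type baseline for relative overrides
    (the defective-COOLAIR f_N0 reduction); defaults are used if omitted.
    """
    base = params if params is not None else ModelParams()
    presets = {
        "wild_type": {},
        "coolair_defective": _defective_overrides(base),
        "ntl8_D3": {"antisense.constitutive": True},
        "nucleation_mutant": {"nucleation_enabled": False,
                              "f_N0": 0.0, "f_S0": 0.0},
        "spreading_mutant": {"spreading_enabled": False},
    }
    if name not in presets:
        raise ParamError(
            f"unknown genotype preset {name!r}; available: "
            + ", ".join(sorted(presets)))
    return GenotypeSpec(name=name, overrides=presets[name])


GENOTYPE_PRESETS = ("wild_type", "coolair_defective", "ntl8_D3",
                    "nucleation_mutant", "spreading_mutant")


def apply_genotype(params: ModelParams, antisense: AntisenseParams,
                   spec: GenotypeSpec | str):
    """Apply a genotype's overrides, returning new (params, antisense).

    The originals are untouched.  The overridden parameter set is
    validated, so an override that breaks a model invariant raises
    ParamError.  Application is idempotent and commutes for disjoint
    override sets.
    """
    if isinstance(spec, str):
        spec = genotype_preset(spec, params)
    new_p = params.copy()
    new_a = antisense.copy()
    for path, value in spec.overrides.items():
        set_param(new_p, new_a, path, value)
    new_p.validate()
    new_a.validate()
    return new_p, new_a
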