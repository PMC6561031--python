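"""Strain presets for the synthetic generator.

Each preset resolves to a fully specified :class:`~icetrack.config.SimConfig`.
The wild-type tc fraction (4.5%) and the ``dmfsR`` regulatory-mutant fraction
(45.4%) are the study's measured subpopulation sizes; excision- and
replication-deficient mutants switch off the corresponding generator
processes:

``dattL``       cannot excise (recombination site deleted) -- foci track the
                chromosomal locus only, so true counts never exceed 2.
``dtraI``       excises but the relaxase-driven copy-number birth process is
                suppressed (rare excursions only).
``doriT1``      like ``dtraI``: the replication origin of transfer is gone.
``doriT2``      the alternative oriT is dispensable for replication; the
                copy-number process is left intact.
``dmfsR``       derepressed activation: large tc subpopulation.
``no_array``    no operator array: nothing for the repressor to bind, zero
                detectable foci (and no reporter-borne spurious foci).
``no_lacI``     array present but no fluorescent repressor: zero detectable
                foci.
"""
from __future__ import annotations

from .config import SimConfig

__all__ = ["preset", "PRESET_NAMES"]

# per-frame copy birth rate for replication-deficient mutants: "plateau at <=2
# with rare excursions"
_SUPPRESSED_BIRTH_RATE = 0.0026

_PRESET_OVERRIDES: dict[str, dict] = {
    "wildtype": {},
    "dmfsR": {"tc_fraction": 0.454},
    "dattL": {"excisable": False},
    "dtraI": {"copy_birth_rate": _SUPPRESSED_BIRTH_RATE},
    "doriT1": {"copy_birth_rate": _SUPPRESSED_BIRTH_RATE},
    "doriT2": {},
    "dmfsR_dtraI": {"tc_fraction": 0.454, "copy_birth_rate": _SUPPRESSED_BIRTH_RATE},
    "dmfsR_dattL": {"tc_fraction": 0.454, "excisable": False},
    "no_array": {"array_present": False, "spurious_pass_rate": 0.0},
    "no_lacI": {"reporter_present": False, "spurious_pass_rate": 0.0},
}

PRESET_NAMES = tuple(sorted(_PRESET_OVERRIDES))


def preset(name: str, **overrides) -> SimConfig:
    """Resolve a strain preset to a :class:`SimConfig`.

    Parameters
    ----------
    name
        One of :data:`PRESET_NAMES`.
    **overrides
        Additional field overrides applied on top of the preset.

    Raises
    ------
    ValueError
        If ``name`` is not a known preset (the message lists valid names).
    """
    if name not in _PRESET_OVERRIDES:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        )
    fields = dict(_PRESET_OVERRIDES[name])
    fields.update(overrides)
    return SimConfig(**fields)
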