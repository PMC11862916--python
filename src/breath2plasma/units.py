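"""Concentration unit conversions for the two matrices."""

from .errors import UnitError

# canonical spellings; a couple of ASCII aliases for the microgram unit
_ALIASES = {
    "ug/mL": "μg/mL",
    "ug/ml": "μg/mL",
    "µg/mL": "μg/mL",
    "ng/ml": "ng/mL",
}

_FACTORS = {
    ("ppbv", "pptv"): 1000.0,
    ("pptv", "ppbv"): 1e-3,
    ("μg/mL", "ng/mL"): 1000.0,
    ("ng/mL", "μg/mL"): 1e-3,
}


def canonical_unit(unit: str) -> str:
    return _ALIASES.get(unit, unit)


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert between gas (ppbv/pptv) or plasma (μg/mL / ng/mL) units.

    Raises UnitError for any pair outside the supported vocabulary.
    """
    fu, tu = canonical_unit(from_unit), canonical_unit(to_unit)
    if fu == tu:
        if fu not in ("ppbv", "pptv", "μg/mL", "ng/mL"):
            raise UnitError(f"unknown unit {from_unit!r}")
        return value
    try:
        return value * _FACTORS[(fu, tu)]
    except KeyError:
        raise UnitError(f"unsupported conversion {from_unit!r} -> {to_unit!r}") from None
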