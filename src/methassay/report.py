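"""Machine-readable pipeline report: structure, serialization, validation.

The report schema is versioned; a JSON copy of the schema ships in-repo
(docs/report.schema.json) and `validate_report` performs the structural
check without external dependencies.
"""

from __future__ import annotations

import json
from typing import Any

SCHEMA_VERSION = "1"

#: Required top-level keys and the required keys of their sub-objects.
SCHEMA: dict[str, Any] = {
    "schema_version": str,
    "seed": int,
    "locus": {"name": str, "length": int, "tss": int, "n_cpg": int},
    "islands": list,  # of {start, end, gc_fraction, obs_exp_cpg, n_cpg}
    "screening": {"group_means": dict, "comparisons": list},
    "designs": list,  # of design objects, ranked
    "cobra": {"enzyme": str, "informative_sites": list,
              "fragments_methylated": list, "fragments_unmethylated": list,
              "group_frequencies_pct": dict},
    "pyro": {"n_cpg_pairs": int, "region_mean_pct": float,
             "per_cpg_pct": dict, "qc_pass": bool, "background_pct": float},
}

_ISLAND_KEYS = {"start", "end", "gc_fraction", "obs_exp_cpg", "n_cpg"}
_DESIGN_KEYS = {
    "rank", "score", "nesting", "amplicon_start", "amplicon_end",
    "amplicon_length", "outer_start", "outer_end", "inner_forward",
    "inner_reverse", "outer_forward", "outer_reverse", "n_cpgs_covered",
    "n_informative_sites", "pyro_window", "pyro_cpg_count",
}


class ReportValidationError(ValueError):
    pass


def validate_report(report: dict) -> None:
    """Structural validation against the in-repo schema; raises
    ReportValidationError on the first problem found."""
    for key, expected in SCHEMA.items():
        if key not in report:
            raise ReportValidationError(f"missing top-level key {key!r}")
        value = report[key]
        if isinstance(expected, dict):
            if not isinstance(value, dict):
                raise ReportValidationError(f"{key!r} must be an object")
            for sub in expected:
                if sub not in value:
                    raise ReportValidationError(f"missing key {key}.{sub}")
        elif isinstance(expected, type):
            if not isinstance(value, expected):
                raise ReportValidationError(
                    f"{key!r} must be {expected.__name__}, got {type(value).__name__}"
                )
        elif expected is list and not isinstance(value, list):
            raise ReportValidationError(f"{key!r} must be a list")
    if report["schema_version"] != SCHEMA_VERSION:
        raise ReportValidationError(
            f"schema version {report['schema_version']!r} != {SCHEMA_VERSION!r}"
        )
    for isl in report["islands"]:
        if set(isl) < _ISLAND_KEYS:
            raise ReportValidationError("island object missing keys")
    for d in report["designs"]:
        if set(d) < _DESIGN_KEYS:
            raise ReportValidationError("design object missing keys")


def dump_report(report: dict, path) -> None:
    """Deterministic serialization: sorted keys, fixed indentation, newline
    at EOF — byte-identical across runs with the same inputs."""
    validate_report(report)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def json_schema() -> dict:
    """The schema as a JSON-Schema-style document (the in-repo copy)."""

    def typename(t: Any) -> dict:
        if t is str:
            return {"type": "string"}
        if t is int:
            return {"type": "integer"}
        if t is list:
            return {"type": "array"}
        if t is dict:
            return {"type": "object"}
        if t is float:
            return {"type": "number"}
        if t is bool:
            return {"type": "boolean"}
        return {"type": "object"}

    props = {}
    for key, expected in SCHEMA.items():
        if isinstance(expected, dict):
            props[key] = {
                "type": "object",
                "required": sorted(expected),
                "properties": {k: typename(v) for k, v in expected.items()},
            }
        else:
            props[key] = typename(expected)
    return {
        "$schema": "http://json-schema.org/draft-07/schema#",
        "title": "methassay pipeline report",
        "type": "object",
        "required": sorted(SCHEMA),
        "properties": props,
    }
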