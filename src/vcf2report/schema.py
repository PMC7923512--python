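"""Structural validation of rendered report documents.

The report schema ships as a JSON-Schema (draft-07) file so reviewers and
external tooling can consume it.  Validation here is done by a small
in-package checker that supports exactly the keywords the shipped schema
uses: ``type``, ``enum``, ``required``, ``properties``, ``items``,
``pattern`` and local ``$ref``.  It intentionally implements nothing more.
"""

from __future__ import annotations

import json
import re
from functools import lru_cache
from importlib import resources

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
}


class SchemaValidationError(ValueError):
    """A document does not conform to the report schema."""


@lru_cache(maxsize=None)
def report_schema() -> dict:
    text = resources.files("vcf2report").joinpath("data/report.schema.json").read_text()
    return json.loads(text)


def _resolve(ref: str, root: dict) -> dict:
    if not ref.startswith("#/"):
        raise SchemaValidationError(f"unsupported $ref {ref!r}")
    node: dict = root
    for part in ref[2:].split("/"):
        node = node[part]
    return node


def _check(instance, schema: dict, root: dict, path: str) -> None:
    if "$ref" in schema:
        _check(instance, _resolve(schema["$ref"], root), root, path)
        return
    if "enum" in schema and instance not in schema["enum"]:
        raise SchemaValidationError(f"{path}: {instance!r} not in {schema['enum']}")
    if "type" in schema:
        expected = _TYPES[schema["type"]]
        if isinstance(instance, bool) and schema["type"] in ("integer", "number"):
            raise SchemaValidationError(f"{path}: expected {schema['type']}, got bool")
        if not isinstance(instance, expected):
            raise SchemaValidationError(
                f"{path}: expected {schema['type']}, got {type(instance).__name__}"
            )
    if "pattern" in schema and isinstance(instance, str):
        if not re.search(schema["pattern"], instance):
            raise SchemaValidationError(
                f"{path}: {instance!r} does not match /{schema['pattern']}/"
            )
    if isinstance(instance, dict):
        for key in schema.get("required", []):
            if key not in instance:
                raise SchemaValidationError(f"{path}: missing required key {key!r}")
        for key, subschema in schema.get("properties", {}).items():
            if key in instance:
                _check(instance[key], subschema, root, f"{path}.{key}")
    if isinstance(instance, list) and "items" in schema:
        for i, item in enumerate(instance):
            _check(item, schema["items"], root, f"{path}[{i}]")


def validate(instance, schema: dict) -> None:
    """Raise :class:`SchemaValidationError` if ``instance`` violates ``schema``."""
    _check(instance, schema, schema, "$")


def validate_report(document: dict) -> None:
    """Validate a rendered report against the shipped structural schema."""
    validate(document, report_schema())
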