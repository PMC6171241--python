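"""Analysis reports: schema, JSON serialization and round-tripping."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .gam import FittedCurve, deviance_explained
from .traits import TraitSet

__all__ = ["FitRecord", "AnalysisReport", "write_report", "read_report",
           "REPORT_SCHEMA", "validate_report_dict"]

# Minimal JSON schema shipped with the package (checked by
# validate_report_dict; kept dependency-free on purpose).
REPORT_SCHEMA = {
    "type": "object",
    "required": ["version", "config", "fits"],
    "properties": {
        "version": {"type": "string"},
        "seed": {"type": ["integer", "null"]},
        "config": {"type": "object"},
        "fits": {
            "type": "array",
            "items": {
                "type": "object",
                "required": ["carbon_source", "response_kind", "diagnostics"],
                "properties": {
                    "carbon_source": {"type": "string"},
                    "response_kind": {"type": "string"},
                    "traits": {"type": ["object", "null"]},
                    "diagnostics": {"type": "object"},
                    "flags": {"type": "array"},
                    "error": {"type": ["string", "null"]},
                },
            },
        },
    },
}

_JSONTYPES = {"object": dict, "array": list, "string": str, "integer": int,
              "number": (int, float), "null": type(None)}


def validate_report_dict(doc: dict, schema: dict = REPORT_SCHEMA, path: str = "$") -> None:
    """Validate a report document against the shipped schema (raises ValueError)."""
    types = schema.get("type")
    if types is not None:
        allowed = tuple(
            t for name in (types if isinstance(types, list) else [types])
            for t in (lambda v: v if isinstance(v, tuple) else (v,))(_JSONTYPES[name])
        )
        if not isinstance(doc, allowed) or isinstance(doc, bool):
            raise ValueError(f"{path}: expected {types}, got {type(doc).__name__}")
    if isinstance(doc, dict):
        for req in schema.get("required", []):
            if req not in doc:
                raise ValueError(f"{path}: missing required key '{req}'")
        for key, sub in schema.get("properties", {}).items():
            if key in doc:
                validate_report_dict(doc[key], sub, f"{path}.{key}")
    if isinstance(doc, list) and "items" in schema:
        for i, item in enumerate(doc):
            validate_report_dict(item, schema["items"], f"{path}[{i}]")


@dataclass(frozen=True)
class FitRecord:
    """One fitted (source, response_kind) entry of a report."""

    carbon_source: str
    response_kind: str
    curve: FittedCurve | None = None
    traits: TraitSet | None = None
    error: str | None = None

    def to_dict(self, sig_digits: int = 4) -> dict:
        rec: dict = {
            "carbon_source": self.carbon_source,
            "response_kind": self.response_kind,
            "traits": None,
            "diagnostics": {},
            "flags": [],
            "error": self.error,
        }
        if self.curve is not None:
            c = self.curve
            rec["diagnostics"] = {
                "edf": round(float(c.edf), 4),
                "deviance": float(c.deviance),
                "null_deviance": float(c.null_deviance),
                "deviance_explained": round(deviance_explained(c), 4),
                "gcv": float(c.gcv),
                "lambda": float(c.lambda_),
                "scale": float(c.scale),
                "link": c.link,
                "basis_kind": c.basis.kind,
                "k": int(c.spec.k),
                "n_obs": int(c.n_obs),
                "domain": list(c.domain),
            }
            rec["flags"] = list(c.flags)
        if self.traits is not None:
            t = self.traits
            sig = lambda v: None if v is None else float(f"%.{sig_digits}g" % v)
            rec["traits"] = {
                "p_max": sig(t.p_max), "t_max": sig(t.t_max),
                "mu": sig(t.mu), "sigma": sig(t.sigma),
                "f_at_pmax": sig(t.f_at_pmax), "f_at_mu": sig(t.f_at_mu),
                "domain_end": sig(t.domain_end),
                "full_precision": {
                    "p_max": t.p_max, "t_max": t.t_max, "mu": t.mu,
                    "sigma": t.sigma, "f_at_pmax": t.f_at_pmax,
                    "f_at_mu": t.f_at_mu,
                },
            }
            rec["flags"] = sorted(set(rec["flags"]) | set(t.flags))
        return rec


@dataclass(frozen=True)
class AnalysisReport:
    """Per-source, per-response fits + traits with run provenance."""

    fits: tuple[FitRecord, ...]
    config: dict = field(default_factory=dict)
    seed: int | None = None
    version: str = "0.1.0"

    def to_dict(self) -> dict:
        cfg = dict(self.config)
        cfg_hash = hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        doc = {
            "version": self.version,
            "seed": self.seed,
            "config": cfg,
            "config_hash": cfg_hash,
            "fits": [f.to_dict() for f in self.fits],
        }
        validate_report_dict(doc)
        return doc

    @property
    def has_errors(self) -> bool:
        return any(f.error for f in self.fits)


def write_report(report: AnalysisReport, path) -> None:
    """Serialize a report to JSON (traits at 4 significant digits plus a
    full-precision block)."""
    if not report.fits:
        raise ValueError("nothing to write: report contains no fits")
    doc = report.to_dict()
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def read_report(path) -> dict:
    """Load and schema-validate a previously written report."""
    with open(path) as fh:
        doc = json.load(fh)
    validate_report_dict(doc)
    return doc
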