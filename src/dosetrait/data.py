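"""Dose-response tables: validation, CSV I/O and packaged study fixtures.

A :class:`DoseResponseTable` holds positive responses (e.g. cell biomass in
g L^-1 or a fatty-acid concentration in mg L^-1) observed at a grid of
dosages of an organic carbon source (percent-points, w/v or v/v).  Tables
come in two layouts:

* *replicate* layout — one row per observation (``dose``, ``response``,
  optional ``replicate`` id);
* *summary* layout — one row per dosage (``dose``, ``response`` = mean,
  ``sd``, ``n``), which is how published tables report triplicates.

The packaged fixtures carry the study's final-day means and standard
deviations for three carbon sources (glucose, sodium acetate, glycerol)
and seven response kinds.  The three dose series shared a single
autotrophic control (dose 0), which the loader prepends to every fixture.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DoseResponseTable",
    "read_dose_response_csv",
    "load_paper_fixture",
    "available_fixtures",
    "pseudo_replicates",
    "FIXTURE_SOURCES",
    "FIXTURE_RESPONSE_KINDS",
]

FIXTURE_SOURCES = ("glucose", "sodium_acetate", "glycerol")
FIXTURE_RESPONSE_KINDS = (
    "biomass",
    "ara_concentration",
    "epa_concentration",
    "tfa_concentration",
    "ara_content",
    "epa_content",
    "tfa_content",
)

RESPONSE_UNITS = {
    "biomass": "g L^-1",
    "ara_concentration": "mg L^-1",
    "epa_concentration": "mg L^-1",
    "tfa_concentration": "mg L^-1",
    "ara_content": "mg g^-1",
    "epa_content": "mg g^-1",
    "tfa_content": "mg g^-1",
}

DOSE_UNITS = {"glucose": "% w/v", "sodium_acetate": "% w/v", "glycerol": "% v/v"}

# Symmetric three-point pattern whose sample mean is the stated mean and
# whose sample SD (ddof=1, the convention for published triplicate SDs) is
# exactly the stated SD.
_PSEUDO_Z = np.array([-1.0, 0.0, 1.0])


class TableValidationError(ValueError):
    """A dose-response table violates a structural invariant."""


@dataclass(frozen=True)
class DoseResponseTable:
    """Validated dose-response observations for one carbon source.

    Parameters
    ----------
    carbon_source
        Label of the dosed substrate (free text; fixtures use ``glucose``,
        ``sodium_acetate`` or ``glycerol``).
    response_kind
        What was measured (``biomass``, ``ara_concentration``, ...).
    frame
        Observations.  Replicate layout needs columns ``dose`` and
        ``response``; summary layout additionally ``sd`` and ``n``.
    dose_unit, response_unit
        Unit labels; metadata only, never used in computation.
    """

    carbon_source: str
    response_kind: str
    frame: pd.DataFrame
    dose_unit: str = "% w/v"
    response_unit: str = ""

    def __post_init__(self) -> None:
        df = self.frame.reset_index(drop=True)
        for col in ("dose", "response"):
            if col not in df.columns:
                raise TableValidationError(
                    f"table '{self.carbon_source}/{self.response_kind}' lacks "
                    f"required column '{col}'"
                )
        if df["dose"].isna().any() or df["response"].isna().any():
            raise TableValidationError("dose/response values must not be missing")
        if (df["dose"] < 0).any():
            raise TableValidationError("negative dose: dosages are >= 0 percent-points")
        if (df["response"] <= 0).any():
            raise TableValidationError(
                "non-positive response: the Gamma observation model requires "
                "strictly positive responses"
            )
        if self.is_summary:
            if (df["sd"] < 0).any():
                raise TableValidationError("negative sd")
            if (df["n"] < 1).any():
                raise TableValidationError("replicate count n must be >= 1")
            if df["dose"].duplicated().any():
                raise TableValidationError(
                    "duplicate dose in summary table: each dosage appears once"
                )
        else:
            counts = df.groupby("dose").size()
            dup_no_rep = (counts > 1).any() and "replicate" not in df.columns
            if dup_no_rep:
                raise TableValidationError(
                    "duplicate dose without replicate ids: add a 'replicate' "
                    "column or collapse to mean/sd/n"
                )
        n_control = int((df["dose"] == 0).sum())
        n_control_unique = int((np.unique(df["dose"]) == 0).sum())
        if n_control_unique != 1:
            raise TableValidationError(
                f"table '{self.carbon_source}/{self.response_kind}' has no "
                "control (dose 0) row; a control is required"
            )
        if self.is_summary and n_control != 1:
            raise TableValidationError("control (dose 0) must appear exactly once")
        df = df.sort_values(["dose"] + (["replicate"] if "replicate" in df else []))
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    # -- layout ---------------------------------------------------------
    @property
    def is_summary(self) -> bool:
        return "sd" in self.frame.columns

    @property
    def doses(self) -> np.ndarray:
        """Unique dosages, strictly increasing."""
        return np.unique(self.frame["dose"].to_numpy(float))

    @property
    def domain_end(self) -> float:
        return float(self.frame["dose"].max())

    @property
    def control_response(self) -> float:
        """Observed mean response at dose 0."""
        at0 = self.frame.loc[self.frame["dose"] == 0, "response"]
        return float(at0.mean())

    def observations(self, mode: str = "auto") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return ``(dose, response, prior_weight)`` arrays for fitting.

        ``mode``:

        * ``"auto"`` — replicate rows as-is; summary tables are expanded to
          pseudo-replicates (the default used for study reproduction).
        * ``"means"`` — summary means with prior weight ``n``.
        * ``"pseudo_replicates"`` — force pseudo-replicate expansion.
        """
        if mode not in ("auto", "means", "pseudo_replicates"):
            raise ValueError(f"unknown fit mode '{mode}'")
        if not self.is_summary:
            d = self.frame["dose"].to_numpy(float)
            y = self.frame["response"].to_numpy(float)
            return d, y, np.ones_like(y)
        if mode == "means":
            d = self.frame["dose"].to_numpy(float)
            y = self.frame["response"].to_numpy(float)
            w = self.frame["n"].to_numpy(float)
            return d, y, w
        rep = pseudo_replicates(self)
        d = rep.frame["dose"].to_numpy(float)
        y = rep.frame["response"].to_numpy(float)
        return d, y, np.ones_like(y)


def pseudo_replicates(table: DoseResponseTable) -> DoseResponseTable:
    """Expand a summary table into deterministic pseudo-replicates.

    Each (mean m, sd s, n=3) row becomes the three values ``m - s, m, m + s``,
    which reproduce the stated mean exactly and the stated SD exactly
    (sample SD, ddof=1).  This is the unique symmetric three-point
    reconstruction and the package's stand-in for unpublished
    replicate-level data.
    """
    if not table.is_summary:
        return table
    rows = []
    for _, r in table.frame.iterrows():
        vals = r["response"] + r["sd"] * _PSEUDO_Z
        if (vals <= 0).any():
            raise TableValidationError(
                f"pseudo-replicate at dose {r['dose']} would be non-positive "
                "(mean too close to zero relative to sd)"
            )
        for j, v in enumerate(vals):
            rows.append({"dose": r["dose"], "response": v, "replicate": j + 1})
    return DoseResponseTable(
        carbon_source=table.carbon_source,
        response_kind=table.response_kind,
        frame=pd.DataFrame(rows),
        dose_unit=table.dose_unit,
        response_unit=table.response_unit,
    )


def read_dose_response_csv(path) -> DoseResponseTable:
    """Read a dose-response table from CSV.

    The header must declare ``dose`` and ``response`` columns; optional
    columns are ``carbon_source``, ``response_kind``, ``sd``, ``n`` and
    ``replicate``.  A ``sd`` column marks the summary layout.
    """
    df = pd.read_csv(path)
    missing = {"dose", "response"} - set(df.columns)
    if missing:
        raise TableValidationError(
            f"{path}: missing required column(s) {sorted(missing)}"
        )
    source = str(df["carbon_source"].iloc[0]) if "carbon_source" in df else "unknown"
    kind = str(df["response_kind"].iloc[0]) if "response_kind" in df else "response"
    keep = [c for c in ("dose", "response", "sd", "n", "replicate") if c in df.columns]
    if "sd" in keep and "n" not in keep:
        df["n"] = 3
        keep.append("n")
    return DoseResponseTable(
        carbon_source=source,
        response_kind=kind,
        frame=df[keep].copy(),
        dose_unit=DOSE_UNITS.get(source, "% w/v"),
        response_unit=RESPONSE_UNITS.get(kind, ""),
    )


def write_dose_response_csv(table: DoseResponseTable, path) -> None:
    """Write a table back to the standard CSV layout (lossless round trip)."""
    df = table.frame.copy()
    df.insert(0, "carbon_source", table.carbon_source)
    df.insert(2, "response_kind", table.response_kind)
    df.to_csv(path, index=False)


def _fixture_frame() -> pd.DataFrame:
    ref = importlib.resources.files("dosetrait") / "fixtures" / "table1.csv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p)


def available_fixtures() -> list[tuple[str, str]]:
    """List the packaged (carbon_source, response_kind) combinations."""
    return [(s, k) for s in FIXTURE_SOURCES for k in FIXTURE_RESPONSE_KINDS]


def load_paper_fixture(source: str, response_kind: str) -> DoseResponseTable:
    """Load one packaged dose-response table (published means +/- SD, n=3).

    The shared autotrophic control (dose 0) is prepended to every table.
    ``response_kind`` accepts short aliases ``ara``/``epa``/``tfa`` for the
    concentration kinds.
    """
    aliases = {"ara": "ara_concentration", "epa": "epa_concentration",
               "tfa": "tfa_concentration"}
    response_kind = aliases.get(response_kind, response_kind)
    if (source, response_kind) not in available_fixtures():
        raise KeyError(
            f"no fixture for ({source!r}, {response_kind!r}); available: "
            f"sources {FIXTURE_SOURCES}, kinds {FIXTURE_RESPONSE_KINDS}"
        )
    df = _fixture_frame()
    sel = df[
        (df["carbon_source"].isin(["control", source]))
        & (df["response_kind"] == response_kind)
    ]
    return DoseResponseTable(
        carbon_source=source,
        response_kind=response_kind,
        frame=sel[["dose", "response", "sd", "n"]].copy(),
        dose_unit=DOSE_UNITS[source],
        response_unit=RESPONSE_UNITS[response_kind],
    )
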