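"""Readers and writers for decoy-energy ensembles and variant record tables.

Energies are binding energies in kcal/mol (more negative = more favorable).
Flat tables are delimited text with a header; docking output is also accepted
in the AutoDock4 DLG log format, from which the final "Estimated Free Energy
of Binding" of each docked run is extracted. Missing numeric cells are kept
as explicit missing values (``None``), never coerced to zero.
"""

from __future__ import annotations

import csv
import json
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, UsageError, ValidationError

__all__ = [
    "DecoyEnsemble",
    "VariantRecord",
    "read_energy_table",
    "parse_autodock_dlg",
    "read_variant_table",
    "write_results",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class DecoyEnsemble:
    """One system's set of docked-pose binding energies (kcal/mol).

    The pose with the lowest energy is taken downstream as the native
    enzyme–substrate complex; all others are decoys.
    """

    system_id: str
    energies: np.ndarray
    pose_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.ndim != 1 or self.energies.size == 0:
            raise ValidationError(
                f"system {self.system_id!r}: energies must be a non-empty 1-D sequence"
            )
        if not np.all(np.isfinite(self.energies)):
            raise ValidationError(
                f"system {self.system_id!r}: every energy must be finite"
            )
        if self.pose_ids is not None:
            if len(self.pose_ids) != self.energies.size:
                raise ValidationError(
                    f"system {self.system_id!r}: pose_ids length "
                    f"{len(self.pose_ids)} != {self.energies.size} energies"
                )
            if len(set(self.pose_ids)) != len(self.pose_ids):
                raise ValidationError(
                    f"system {self.system_id!r}: pose_ids must be unique"
                )

    def __len__(self) -> int:
        return int(self.energies.size)


@dataclass
class VariantRecord:
    """One enzyme variant: ISR, ΔG_bind, ΔG‡ and ln(kcat/Km), any of which may be missing.

    ``binding_affinity`` is ΔG_bind in kcal/mol (negative = favorable);
    ``reaction_barrier`` is the catalytic barrier ΔG‡ in kcal/mol;
    ``ln_activity`` is ln(kcat/Km), unit-less up to a reference state.
    """

    variant_id: str
    isr: float | None = None
    binding_affinity: float | None = None
    reaction_barrier: float | None = None
    ln_activity: float | None = None
    is_wild_type: bool = False


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _as_text_handle(source: str | Path | IO[str]) -> IO[str]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8", newline="")
    return source


def _read_frame(source: str | Path | IO[str], delimiter: str) -> pd.DataFrame:
    handle = _as_text_handle(source)
    try:
        frame = pd.read_csv(handle, sep=delimiter, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise FormatError("empty file: expected a delimited table with a header")
    finally:
        if handle is not source:
            handle.close()
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    return frame


def _numeric_column(frame: pd.DataFrame, column: str) -> np.ndarray:
    """Parse a string column to float, reporting the first bad 1-based file line.

    Uses Python's correctly rounded float parser so that values written with
    ``repr`` round-trip bit-identically.
    """
    out = np.empty(len(frame), dtype=float)
    for idx, token in enumerate(frame[column]):
        if token is None or (isinstance(token, float) and math.isnan(token)):
            out[idx] = math.nan
            continue
        token = str(token).strip()
        if token == "":
            out[idx] = math.nan
            continue
        try:
            out[idx] = float(token)
        except ValueError:
            # +2: one for the header line, one for 1-based numbering
            raise ParseError(
                f"column {column!r}: cannot parse {token!r} as a number",
                line=idx + 2,
            )
    return out


def read_energy_table(
    source: str | Path | IO[str], delimiter: str = ","
) -> list[DecoyEnsemble]:
    """Read a long-format energy table into one :class:`DecoyEnsemble` per system.

    The table must have a header naming at least ``system`` and ``energy``
    columns (an optional ``pose`` column supplies pose labels). One ensemble
    is returned per distinct system, in order of first appearance; energies
    keep file order.
    """
    frame = _read_frame(source, delimiter)
    for required in ("system", "energy"):
        if required not in frame.columns:
            raise FormatError(f"missing required column {required!r}")
    if len(frame) == 0:
        raise FormatError("energy table has a header but no rows")
    energies = _numeric_column(frame, "energy")
    systems = frame["system"].astype(str).to_numpy()
    poses = frame["pose"].astype(str).to_numpy() if "pose" in frame.columns else None

    out: list[DecoyEnsemble] = []
    for system in pd.unique(systems):
        mask = systems == system
        out.append(
            DecoyEnsemble(
                system_id=str(system),
                energies=energies[mask],
                pose_ids=list(poses[mask]) if poses is not None else None,
            )
        )
    return out


_DLG_RUN = re.compile(r"^DOCKED:\s*USER\s*Run\s*=\s*(\d+)", re.IGNORECASE)
_DLG_ENERGY = re.compile(
    r"^DOCKED:\s*USER\s*Estimated Free Energy of Binding\s*=\s*(\S+)",
    re.IGNORECASE,
)


def parse_autodock_dlg(
    source: str | Path | IO[str], system_id: str | None = None
) -> DecoyEnsemble:
    """Extract per-run binding energies from an AutoDock4 DLG log.

    Only the final "Estimated Free Energy of Binding" line of each
    DOCKED-prefixed block is used — the per-pose score AutoDock ranks by.
    Run numbers become pose ids; poses keep file order.
    """
    handle = _as_text_handle(source)
    try:
        name = system_id
        if name is None:
            name = Path(getattr(handle, "name", "dlg")).stem
        energies: list[float] = []
        pose_ids: list[str] = []
        current_run: str | None = None
        for lineno, line in enumerate(handle, start=1):
            m = _DLG_RUN.match(line)
            if m:
                current_run = m.group(1)
                continue
            m = _DLG_ENERGY.match(line)
            if m:
                try:
                    value = float(m.group(1))
                except ValueError:
                    raise ParseError(
                        f"malformed DLG energy field {m.group(1)!r}", line=lineno
                    )
                energies.append(value)
                run = current_run if current_run is not None else str(len(energies))
                pose_ids.append(f"run_{run}")
                current_run = None
    finally:
        if handle is not source:
            handle.close()
    if not energies:
        raise FormatError("no DOCKED 'Estimated Free Energy of Binding' lines found")
    if len(set(pose_ids)) != len(pose_ids):  # duplicated run numbers in a merged log
        pose_ids = [f"run_{i + 1}" for i in range(len(energies))]
    return DecoyEnsemble(system_id=name, energies=np.array(energies), pose_ids=pose_ids)


_TRUE_TOKENS = {"true", "t", "yes", "y", "1", "1.0"}
_FALSE_TOKENS = {"false", "f", "no", "n", "0", "0.0", ""}

_VARIANT_ALIASES = {
    "isr": "isr",
    "affinity": "binding_affinity",
    "binding_affinity": "binding_affinity",
    "barrier": "reaction_barrier",
    "reaction_barrier": "reaction_barrier",
    "ln_activity": "ln_activity",
    "activity": "ln_activity",
}


def read_variant_table(
    source: str | Path | IO[str], delimiter: str = ","
) -> list[VariantRecord]:
    """Read a per-variant record table.

    Requires a ``variant`` column; any subset of ``isr``, ``affinity``,
    ``barrier``, ``ln_activity`` and ``wild_type`` may follow. Absent columns
    and empty cells become missing fields. When no ``wild_type`` column is
    given, a variant literally named "WT" (case-insensitive) is flagged.
    """
    frame = _read_frame(source, delimiter)
    if "variant" not in frame.columns:
        raise FormatError("missing required column 'variant'")
    if len(frame) == 0:
        raise FormatError("variant table has a header but no rows")

    variants = frame["variant"].astype(str).str.strip()
    dupes = variants[variants.duplicated()]
    if len(dupes):
        raise ValidationError(f"duplicate variant_id {dupes.iloc[0]!r}")

    numeric: dict[str, np.ndarray] = {}
    for column, attr in _VARIANT_ALIASES.items():
        if column in frame.columns and attr not in numeric:
            numeric[attr] = _numeric_column(frame, column)

    if "wild_type" in frame.columns:
        flags: list[bool] = []
        for i, token in enumerate(frame["wild_type"]):
            token = "" if pd.isna(token) else str(token).strip().lower()
            if token in _TRUE_TOKENS:
                flags.append(True)
            elif token in _FALSE_TOKENS:
                flags.append(False)
            else:
                raise ParseError(
                    f"column 'wild_type': cannot parse {token!r} as a boolean",
                    line=i + 2,
                )
    else:
        flags = [v.upper() == "WT" for v in variants]
    if sum(flags) > 1:
        ids = [v for v, f in zip(variants, flags) if f]
        raise ValidationError(f"more than one wild-type record: {', '.join(ids)}")

    records = []
    for i, variant in enumerate(variants):
        values = {
            attr: (None if math.isnan(col[i]) else float(col[i]))
            for attr, col in numeric.items()
        }
        records.append(VariantRecord(variant_id=variant, is_wild_type=flags[i], **values))
    return records


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _variant_row(r) -> dict:
    return {
        "variant": r.variant_id,
        "isr": r.isr,
        "affinity": r.binding_affinity,
        "barrier": r.reaction_barrier,
        "ln_activity": r.ln_activity,
        "wild_type": r.is_wild_type,
    }


def _rows_for(payload: Sequence) -> tuple[list[str], list[dict]]:
    # local imports avoid a cycle: landscape/analysis both build on io types
    from .landscape_core import IsrInterval, LandscapeStats
    from .specificity_analysis import AnalysisResult, HotSpotCall

    first = payload[0]
    if isinstance(first, VariantRecord):
        rows = [_variant_row(r) for r in payload]
    elif isinstance(first, DecoyEnsemble):
        rows = []
        for ens in payload:
            for i, e in enumerate(ens.energies):
                pose = ens.pose_ids[i] if ens.pose_ids is not None else f"pose_{i + 1}"
                rows.append({"system": ens.system_id, "energy": float(e), "pose": pose})
    elif isinstance(first, LandscapeStats):
        rows = [
            {
                "system": s.system_id,
                "e_native": s.e_native,
                "mean_decoy": s.mean_decoy,
                "delta_gap": s.delta_gap,
                "roughness": s.roughness,
                "entropy_term": s.entropy_term,
                "isr": s.isr,
                "n_total": s.n_total,
                "n_decoys": s.n_decoys,
            }
            for s in payload
        ]
    elif isinstance(first, IsrInterval):
        rows = [
            {
                "point": s.point,
                "lower": s.lower,
                "upper": s.upper,
                "level": s.level,
                "n_boot": s.n_boot,
                "n_degenerate": s.n_degenerate,
                "seed": s.seed,
            }
            for s in payload
        ]
    elif isinstance(first, AnalysisResult):
        rows = [
            {
                "x_field": a.x_field,
                "y_field": a.y_field,
                "subset_rule": a.subset_rule,
                "n_used": a.n_used,
                "pearson_r": a.pearson_r,
                "slope": a.slope,
                "intercept": a.intercept,
            }
            for a in payload
        ]
    elif isinstance(first, HotSpotCall):
        rows = [
            {
                "variant": c.variant_id,
                "isr": c.isr,
                "threshold": c.threshold,
                "is_hot_spot": c.is_hot_spot,
            }
            for c in payload
        ]
    else:
        raise UsageError(f"cannot serialize payload of type {type(first).__name__}")
    return list(rows[0].keys()), rows


_EMPTY_HEADER = ["variant", "isr", "affinity", "barrier", "ln_activity", "wild_type"]


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "True" if value else "False"
    if isinstance(value, float):
        return repr(value)  # repr round-trips IEEE doubles exactly
    return str(value)


def write_results(
    payload: Sequence,
    destination: str | Path | IO[str],
    format: str = "csv",
    kind: str | None = None,
) -> None:
    """Write records, stats or analysis results as CSV or JSON.

    Column order is fixed per payload type; floats are serialized with full
    round-trip precision, missing values as empty cells (CSV) or ``null``
    (JSON). JSON output is a list of flat objects.
    """
    if format not in ("csv", "json"):
        raise UsageError(f"unknown output format {format!r}; expected 'csv' or 'json'")
    if len(payload) == 0:
        header = {"variant": _EMPTY_HEADER}.get(kind or "variant", _EMPTY_HEADER)
        rows: list[dict] = []
    else:
        header, rows = _rows_for(payload)

    own = isinstance(destination, (str, Path))
    handle = open(destination, "w", encoding="utf-8", newline="") if own else destination
    try:
        if format == "csv":
            writer = csv.writer(handle)
            writer.writerow(header)
            for row in rows:
                writer.writerow([_format_cell(row[c]) for c in header])
        else:
            json.dump(rows, handle, indent=2, allow_nan=False)
            handle.write("\n")
    finally:
        if own:
            handle.close()
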