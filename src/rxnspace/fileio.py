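"""CSV interchange formats: rule files, molecule tables, peaks and adducts.

Rule files carry columns ``rule_id, smarts, diameter, ec`` (ec optional,
semicolon-separated).  Molecule tables carry ``name, structure`` where the
structure is SMILES or InChI.  Peak lists carry ``mz, intensity`` and
adduct tables ``name, mass_shift, charge, mode``.
"""

from __future__ import annotations

import io
import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .chem import Molecule, MoleculeError, ReactionRule, RuleError, parse_molecule
from .masses import Adduct, Peak

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised for malformed input files, citing the offending line."""


def _read_csv(path, **kwargs) -> pd.DataFrame:
    """CSV reader that skips full-line ``#`` comments only.

    A column-wise comment character would truncate SMARTS strings at every
    triple bond, so only lines *starting* with ``#`` are treated as header
    commentary.
    """
    with open(path) as fh:
        body = "".join(line for line in fh if not line.lstrip().startswith("#"))
    return pd.read_csv(io.StringIO(body), **kwargs)


def _diameter_from_text(text) -> float:
    if text is None or (isinstance(text, float) and math.isnan(text)) or text == "":
        return float("inf")
    if str(text).lower() in ("inf", "infinity"):
        return float("inf")
    return float(text)


def read_rules(path) -> list:
    """Parse a rule CSV into :class:`ReactionRule` objects.

    Raises :class:`FormatError` with the line number for a missing smarts
    column or an unparsable SMARTS.
    """
    df = _read_csv(path, dtype=str)
    if df.empty and "smarts" not in df.columns:
        logger.warning("rule file %s is empty", path)
        return []
    if "smarts" not in df.columns:
        raise FormatError(f"{path}: missing required column 'smarts'")
    rules = []
    for row_idx, row in df.iterrows():
        line_no = row_idx + 2  # 1-based, after the header
        rule_id = row.get("rule_id") or f"rule{row_idx + 1}"
        ec = row.get("ec")
        ec_list = [e for e in str(ec).split(";") if e and e != "nan"] if pd.notna(ec) else []
        try:
            rules.append(
                ReactionRule(
                    rule_id=str(rule_id),
                    smarts=str(row["smarts"]),
                    diameter=_diameter_from_text(row.get("diameter")),
                    ec_annotations=ec_list,
                )
            )
        except RuleError as exc:
            raise FormatError(f"{path}, line {line_no}: {exc}") from exc
    return rules


def write_rules(rules: Iterable[ReactionRule], path, header_lines: Sequence[str] = ()):
    """Write rules to CSV, round-trip stable with :func:`read_rules`."""
    rows = [
        {
            "rule_id": r.rule_id,
            "smarts": r.smarts,
            "diameter": "inf" if math.isinf(r.diameter) else int(r.diameter),
            "ec": ";".join(r.ec_annotations),
        }
        for r in rules
    ]
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        pd.DataFrame(rows, columns=["rule_id", "smarts", "diameter", "ec"]).to_csv(
            fh, index=False
        )


def read_molecule_table(path) -> list:
    """Parse a name,structure CSV into (name, Molecule) pairs.

    Unparsable rows are skipped with a logged warning; rows duplicating an
    already-seen connectivity are merged (first name wins).
    """
    df = _read_csv(path, dtype=str)
    for col in ("name", "structure"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    out = []
    seen = {}
    for row_idx, row in df.iterrows():
        try:
            mol = parse_molecule(str(row["structure"]))
        except MoleculeError as exc:
            logger.warning("%s, row %d skipped: %s", path, row_idx + 2, exc)
            continue
        key = mol.canonical_key
        if key in seen:
            logger.warning(
                "%s, row %d: %r duplicates %r at the connectivity level; merged",
                path, row_idx + 2, row["name"], seen[key],
            )
            continue
        seen[key] = str(row["name"])
        out.append((str(row["name"]), mol))
    return out


def write_molecule_table(pairs: Iterable[tuple], path, header_lines: Sequence[str] = ()):
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        pd.DataFrame(
            [{"name": n, "structure": m.canonical_key} for n, m in pairs]
        ).to_csv(fh, index=False)


def read_peaks(path) -> list:
    df = _read_csv(path)
    if "mz" not in df.columns:
        raise FormatError(f"{path}: missing required column 'mz'")
    intensity = df["intensity"] if "intensity" in df.columns else [0.0] * len(df)
    return [Peak(float(mz), float(i)) for mz, i in zip(df["mz"], intensity)]


def read_adducts(path) -> list:
    df = _read_csv(path)
    for col in ("name", "mass_shift", "charge"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    out = []
    for _, row in df.iterrows():
        charge = int(row["charge"])
        mode = row.get("mode") or ("positive" if charge > 0 else "negative")
        out.append(Adduct(str(row["name"]), float(row["mass_shift"]), charge, str(mode)))
    return out
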