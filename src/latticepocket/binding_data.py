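"""Thermal-shift table parsing and pocket-dependence calls.

A thermal-shift assay measures the ligand-induced increase of a protein's
melting temperature (delta-Tm).  Running the same peptide against the
wild-type protein and against a pocket-ablating double mutant (Y417A/Y421A
in the packaged fixture) and differencing the two shifts isolates the
contribution of the hydrophobic pocket to binding: a peptide whose shift
drops substantially on the mutant depends on the pocket.

Differences are computed with decimal arithmetic at the precision of the
input, so a table printing one decimal place reproduces its printed delta
column exactly.  ITC columns (K_D, delta-H) are carried through verbatim;
they are measured quantities and are never computed or fitted here.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, InvalidOperation
from importlib import resources
from pathlib import Path

DEFAULT_DEPENDENCE_THRESHOLD = 2.0  # degrees C


class ShiftTableError(ValueError):
    pass


@dataclass
class ThermalShiftRecord:
    """One table row: peptide, wild-type and pocket-mutant delta-Tm."""

    peptide: str
    tm_shift_wt: float
    tm_shift_mut: float
    delta: float
    pocket_dependent: bool
    kd_um: float | None = None
    dh_kcal: float | None = None


def call_pocket_dependence(record: ThermalShiftRecord,
                           threshold: float = DEFAULT_DEPENDENCE_THRESHOLD) -> bool:
    """True iff the wild-type-minus-mutant shift difference >= threshold.

    A plain threshold rule, not a statistical test: shift tables of this kind
    typically come without replicate errors.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    return record.delta >= threshold


def _decimal(text: str, row: int, column: str) -> Decimal:
    try:
        return Decimal(text)
    except InvalidOperation:
        raise ShiftTableError(
            f"row {row}: non-numeric {column} value {text!r}"
        ) from None


def read_shift_table(path: str | Path,
                     threshold: float = DEFAULT_DEPENDENCE_THRESHOLD
                     ) -> list[ThermalShiftRecord]:
    """Read a delimited shift table (TSV; header required).

    Columns: ``peptide``, ``tm_shift_wt``, ``tm_shift_mut``, and optionally
    ``kd_um`` and ``dh_kcal``.  Delta and the pocket-dependence call are
    derived on reading; delta is exact to the input's printed precision.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ShiftTableError(f"{path.name}: empty table")
    header = [h.strip() for h in lines[0].split("\t")]
    required = ("peptide", "tm_shift_wt", "tm_shift_mut")
    for col in required:
        if col not in header:
            raise ShiftTableError(f"{path.name}: missing column {col!r}")
    idx = {name: header.index(name) for name in header}

    records: list[ThermalShiftRecord] = []
    for row_num, line in enumerate(lines[1:], start=2):
        fields = [f.strip() for f in line.split("\t")]
        get = lambda col: fields[idx[col]] if col in idx and idx[col] < len(fields) else ""
        wt = _decimal(get("tm_shift_wt"), row_num, "tm_shift_wt")
        mut = _decimal(get("tm_shift_mut"), row_num, "tm_shift_mut")
        delta = wt - mut
        kd = get("kd_um")
        dh = get("dh_kcal")
        kd_um = float(_decimal(kd, row_num, "kd_um")) if kd else None
        if kd_um is not None and kd_um <= 0:
            raise ShiftTableError(f"row {row_num}: K_D must be positive, got {kd_um}")
        rec = ThermalShiftRecord(
            peptide=get("peptide"),
            tm_shift_wt=float(wt),
            tm_shift_mut=float(mut),
            delta=float(delta),
            pocket_dependent=False,
            kd_um=kd_um,
            dh_kcal=float(_decimal(dh, row_num, "dh_kcal")) if dh else None,
        )
        rec.pocket_dependent = call_pocket_dependence(rec, threshold)
        records.append(rec)
    return records


def packaged_shift_table() -> Path:
    """Path of the bundled wild-type vs Y417A/Y421A peptide shift fixture."""
    ref = resources.files("latticepocket") / "data" / "table1.tsv"
    with resources.as_file(ref) as p:
        return Path(p)


def write_shift_table(records: list[ThermalShiftRecord], path: str | Path) -> None:
    """Serialize records back to the TSV dialect read_shift_table accepts."""
    def fmt(x: float | None) -> str:
        return "" if x is None else f"{x:g}"

    with open(path, "w") as fh:
        fh.write("peptide\ttm_shift_wt\ttm_shift_mut\tkd_um\tdh_kcal\n")
        for r in records:
            fh.write(f"{r.peptide}\t{r.tm_shift_wt:g}\t{r.tm_shift_mut:g}\t"
                     f"{fmt(r.kd_um)}\t{fmt(r.dh_kcal)}\n")
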