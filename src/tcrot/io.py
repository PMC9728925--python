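"""Clonotype tables, repertoires, and the germline CDR loop table.

A TCRβ clonotype is identified by a TRBV allele plus a CDR3 amino-acid
sequence; J genes are excluded because their contribution to binding
specificity is carried by the CDR3 itself.  Repertoires are ordered
collections of clonotypes with abundances and a derived probability-mass
vector.  The germline table maps each TRBV allele to the three
germline-encoded loops (CDR1β, CDR2β, CDR2.5β) that enter the TCRdist
metric alongside the CDR3.

The bundled loop table (``data/germline_trbv_synthetic.tsv``) is a
deterministic synthetic stand-in with IMGT-style allele names and
fixed-length loops (CDR1: 7, CDR2: 8, CDR2.5: 6; interior ``-`` gap
characters permitted).  It is not derived from real germline sequence;
supply your own table via :meth:`GermlineCdrTable.from_tsv` for analyses
where the actual loop residues matter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputFormatError, ResolutionError, ValidationError

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

_V_COL_NAMES = ("v_allele", "v_gene", "v", "vgene", "v_call")
_CDR3_COL_NAMES = ("cdr3", "cdr3aa", "cdr3_aa", "junction_aa", "cdr3b")
_COUNT_COL_NAMES = ("count", "counts", "abundance", "templates", "clone_count")

#: fixed loop lengths declared by the bundled table's boundary convention
LOOP_LENGTHS = {"cdr1": 7, "cdr2": 8, "cdr2_5": 6}


@dataclass(frozen=True)
class TcrBeta:
    """A TCRβ clonotype: TRBV allele name + CDR3 amino-acid sequence."""

    v_allele: str
    cdr3: str

    def __post_init__(self) -> None:
        if not self.cdr3:
            raise ValidationError("CDR3 sequence must be non-empty")
        bad = set(self.cdr3) - set(AA_ALPHABET)
        if bad:
            raise ValidationError(
                f"CDR3 {self.cdr3!r} contains non-amino-acid characters: "
                f"{sorted(bad)}"
            )

    def key(self) -> tuple[str, str]:
        return (self.v_allele, self.cdr3)


@dataclass
class Repertoire:
    """An ordered sample of TCRβ clonotypes with abundances and mass.

    ``mass`` is the probability vector used by the transport solver:
    uniform per row by default (clonal abundance ignored, the conservative
    convention for clonotype-collapsed input), or proportional to counts.
    """

    tcrs: list[TcrBeta]
    abundances: np.ndarray
    mass: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=np.int64)
        self.mass = np.asarray(self.mass, dtype=np.float64)
        if not (len(self.tcrs) == len(self.abundances) == len(self.mass)):
            raise ValidationError("tcrs, abundances and mass must have equal length")
        if len(self.tcrs) == 0:
            return
        if np.any(self.abundances <= 0):
            raise ValidationError("abundances must be positive integers")
        if np.any(self.mass < 0) or abs(self.mass.sum() - 1.0) > 1e-9:
            raise ValidationError("mass must be non-negative and sum to 1")

    def __len__(self) -> int:
        return len(self.tcrs)

    @classmethod
    def from_tcrs(
        cls,
        tcrs: Iterable[TcrBeta],
        abundances: Sequence[int] | None = None,
        weighting: str = "uniform",
        label: str = "",
    ) -> "Repertoire":
        tcrs = list(tcrs)
        n = len(tcrs)
        if abundances is None:
            abundances = np.ones(n, dtype=np.int64)
        else:
            abundances = np.asarray(list(abundances), dtype=np.int64)
        if weighting == "uniform":
            mass = np.full(n, 1.0 / n) if n else np.empty(0)
        elif weighting == "abundance":
            mass = abundances / abundances.sum() if n else np.empty(0)
        else:
            raise ValidationError(f"unknown weighting {weighting!r}")
        return cls(tcrs, abundances, mass, label=label)

    def deduplicated(self) -> "Repertoire":
        """Collapse duplicate (V, CDR3) rows, summing counts.

        Mass weighting is recomputed as uniform over the unique clonotypes.
        """
        seen: dict[tuple[str, str], int] = {}
        tcrs: list[TcrBeta] = []
        counts: list[int] = []
        for t, a in zip(self.tcrs, self.abundances):
            k = t.key()
            if k in seen:
                counts[seen[k]] += int(a)
            else:
                seen[k] = len(tcrs)
                tcrs.append(t)
                counts.append(int(a))
        return Repertoire.from_tcrs(tcrs, counts, weighting="uniform", label=self.label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "v_allele": [t.v_allele for t in self.tcrs],
                "cdr3": [t.cdr3 for t in self.tcrs],
                "count": self.abundances,
                "mass": self.mass,
            }
        )


class GermlineCdrTable:
    """Mapping from TRBV allele to fixed-length CDR1/CDR2/CDR2.5 loops.

    Resolution applies TCRdist-style fallbacks: a bare gene name resolves
    to its ``*01`` allele, and an unknown allele of a known gene falls back
    to ``*01`` with a logged warning.
    """

    def __init__(self, loops: dict[str, tuple[str, str, str]]):
        for allele, (c1, c2, c25) in loops.items():
            for name, seq in zip(("cdr1", "cdr2", "cdr2_5"), (c1, c2, c25)):
                if len(seq) != LOOP_LENGTHS[name]:
                    raise ValidationError(
                        f"{allele}: {name} loop {seq!r} has length {len(seq)}, "
                        f"expected {LOOP_LENGTHS[name]}"
                    )
                bad = set(seq) - set(AA_ALPHABET) - {GAP}
                if bad:
                    raise ValidationError(f"{allele}: invalid loop characters {bad}")
        self._loops = dict(loops)

    def __contains__(self, allele: str) -> bool:
        try:
            self.resolve_allele(allele)
            return True
        except ResolutionError:
            return False

    @property
    def alleles(self) -> list[str]:
        return sorted(self._loops)

    def resolve_allele(self, allele: str) -> str:
        """Return the table key this allele name resolves to."""
        if allele in self._loops:
            return allele
        if "*" not in allele:
            candidate = allele + "*01"
            if candidate in self._loops:
                return candidate
        else:
            gene = allele.split("*", 1)[0]
            candidate = gene + "*01"
            if candidate in self._loops:
                logger.warning(
                    "allele %s not in germline table; falling back to %s",
                    allele,
                    candidate,
                )
                return candidate
        raise ResolutionError(f"cannot resolve TRBV allele {allele!r}")

    def loops(self, allele: str) -> tuple[str, str, str]:
        return self._loops[self.resolve_allele(allele)]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GermlineCdrTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"v_allele", "cdr1", "cdr2", "cdr2_5"}
        missing = required - set(df.columns)
        if missing:
            raise InputFormatError(f"germline table missing columns: {sorted(missing)}")
        return cls(
            {
                r.v_allele: (r.cdr1, r.cdr2, r.cdr2_5)
                for r in df.itertuples(index=False)
            }
        )

    @classmethod
    def default(cls) -> "GermlineCdrTable":
        """The bundled synthetic loop table (see module docstring)."""
        with resources.as_file(
            resources.files("tcrot.data") / "germline_trbv_synthetic.tsv"
        ) as p:
            return cls.from_tsv(p)


def resolve_cdr_loops(
    tcr: TcrBeta, table: GermlineCdrTable
) -> tuple[str, str, str, str]:
    """Return the four loops entering TCRdist: (CDR1β, CDR2β, CDR2.5β, CDR3β)."""
    c1, c2, c25 = table.loops(tcr.v_allele)
    return (c1, c2, c25, tcr.cdr3)


def _find_column(columns: Sequence[str], candidates: Sequence[str]) -> str | None:
    lower = {c.lower().strip(): c for c in columns}
    for cand in candidates:
        if cand in lower:
            return lower[cand]
    return None


def load_repertoire(
    path: str | Path,
    weighting: str = "uniform",
    label: str | None = None,
    table: GermlineCdrTable | None = None,
    deduplicate: bool = False,
) -> Repertoire:
    """Read a clonotype table (TSV or CSV, header required).

    Required columns (case-insensitive): a V column (``v_gene`` /
    ``v_allele``) and a CDR3 column (``cdr3`` / ``cdr3aa``); an optional
    count column.  When ``table`` is given, every V allele is checked to be
    resolvable against it.  Duplicate rows are kept as separate entries
    unless ``deduplicate`` is set (the randomization test relies on
    per-occurrence rows).
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    v_col = _find_column(df.columns, _V_COL_NAMES)
    cdr3_col = _find_column(df.columns, _CDR3_COL_NAMES)
    if v_col is None or cdr3_col is None:
        raise InputFormatError(
            f"{path}: need a V column ({'/'.join(_V_COL_NAMES)}) and a CDR3 "
            f"column ({'/'.join(_CDR3_COL_NAMES)}); found {list(df.columns)}"
        )
    count_col = _find_column(df.columns, _COUNT_COL_NAMES)

    tcrs: list[TcrBeta] = []
    bad_rows: list[str] = []
    for idx, (v, c) in enumerate(zip(df[v_col].astype(str), df[cdr3_col].astype(str))):
        try:
            tcrs.append(TcrBeta(v.strip(), c.strip()))
        except ValidationError as e:
            bad_rows.append(f"row {idx + 2}: {e}")  # +2: header + 1-based
    if bad_rows:
        raise ValidationError(
            f"{path}: invalid clonotypes:\n" + "\n".join(bad_rows[:20])
        )
    if table is not None:
        for idx, t in enumerate(tcrs):
            try:
                table.resolve_allele(t.v_allele)
            except ResolutionError as e:
                raise ResolutionError(f"{path} row {idx + 2}: {e}") from None

    counts = (
        pd.to_numeric(df[count_col]).astype(int).to_numpy()
        if count_col is not None
        else None
    )
    rep = Repertoire.from_tcrs(
        tcrs, counts, weighting=weighting, label=label or path.stem
    )
    return rep.deduplicated() if deduplicate else rep


SCORE_COLUMNS = [
    "v_allele",
    "cdr3",
    "individual_loneliness",
    "neighborhood_loneliness",
    "neighbor_count",
    "cluster_id",
    "p_value",
]


def write_scores_table(scores: pd.DataFrame, path: str | Path) -> None:
    """Write a per-TCR score table as TSV (missing entries as NA).

    The frame must carry at least ``v_allele``, ``cdr3``,
    ``individual_loneliness`` and ``neighborhood_loneliness``; optional
    ``cluster_id`` / ``p_value`` columns are filled with NA when absent.
    Round-trips through :func:`read_scores_table` to 1e-9.
    """
    out = scores.copy()
    for col in SCORE_COLUMNS:
        if col not in out.columns:
            out[col] = pd.NA
    out = out[SCORE_COLUMNS]
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.12g")


def read_scores_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
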