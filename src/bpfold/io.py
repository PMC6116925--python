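"""Input/output helpers: FASTA reading, fixture generation, table export.

FASTA parsing goes through Biopython; sequences are normalized to
uppercase RNA (T mapped to U) and any other character is rejected with
its position.  Matrix export covers the triangular DP tables, the hybrid
prefix matrix and dot-plots, as TSV (via pandas) or JSON.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import pandas as pd
from Bio import SeqIO

from .count import CountMatrix
from .ensemble import DotPlot, PartitionMatrices
from .fold import ScoreMatrix
from .interaction import HybridMatrix
from .model import RNA_ALPHABET, RnaError, RnaSequence


def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read all records of a FASTA file as normalized RNA sequences."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise RnaError(f"no FASTA records in {path}")
    sequences = []
    for rec in records:
        raw = str(rec.seq).strip().upper().replace("T", "U")
        for pos, ch in enumerate(raw, start=1):
            if ch not in RNA_ALPHABET:
                raise RnaError(
                    f"record {rec.id!r}: illegal residue {ch!r} at position {pos}"
                )
        sequences.append(RnaSequence(raw))
    return sequences


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic random-sequence generator settings."""

    count: int = 10
    length_range: tuple[int, int] = (5, 12)
    gc_bias: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise ValueError("length_range must satisfy 0 < lo <= hi")
        if not 0.0 <= self.gc_bias <= 1.0:
            raise ValueError("gc_bias must lie in [0, 1]")


#: canonical teaching inputs used throughout the test-suite and examples
NAMED_FIXTURES: dict[str, Any] = {
    "single-pair": "GAAAC",
    "hairpin": "GGGAAACCC",
    "interaction": ("CCC", "CCCGGGGGG"),
}


def generate_fixtures(spec: FixtureSpec) -> list[RnaSequence]:
    """Seeded random RNA sequences; identical spec => identical output."""
    rng = random.Random(spec.seed)
    out = []
    for _ in range(spec.count):
        length = rng.randint(*spec.length_range)
        bases = []
        for _ in range(length):
            if rng.random() < spec.gc_bias:
                bases.append(rng.choice("GC"))
            else:
                bases.append(rng.choice("AU"))
        out.append(RnaSequence("".join(bases)))
    return out


def named_fixture(name: str):
    """Look up a canonical input; pairs are returned as (S1, S2) tuples."""
    if name not in NAMED_FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; have {sorted(NAMED_FIXTURES)}")
    value = NAMED_FIXTURES[name]
    if isinstance(value, tuple):
        return tuple(RnaSequence(v) for v in value)
    return RnaSequence(value)


# ---------------------------------------------------------------------------
# table export
# ---------------------------------------------------------------------------

def _triangular_frame(n: int, getter, fmt=lambda v: v) -> pd.DataFrame:
    index = list(range(1, n + 1))
    data = {
        j: [fmt(getter(i, j)) if i <= j else "" for i in index] for j in index
    }
    frame = pd.DataFrame(data, index=index)
    frame.index.name = "i"
    frame.columns.name = "j"
    return frame


def matrix_frame(table, precision: int | None = None) -> pd.DataFrame:
    """Any supported DP table as a 1-based DataFrame (counts as exact
    integer strings, reals optionally rounded)."""
    if isinstance(table, CountMatrix):
        return _triangular_frame(table.n, table.value, fmt=str)
    if isinstance(table, ScoreMatrix):
        fmt = (lambda v: round(v, precision)) if precision is not None else (lambda v: v)
        return _triangular_frame(table.n, table.value, fmt=fmt)
    if isinstance(table, PartitionMatrices):
        fmt = (lambda v: round(v, precision)) if precision is not None else (lambda v: v)
        return _triangular_frame(table.n, table.q_value, fmt=fmt)
    if isinstance(table, HybridMatrix):
        frame = pd.DataFrame(
            [list(row) for row in table.h],
            index=list(range(table.n + 1)),
            columns=list(range(table.m + 1)),
        )
        frame.index.name = "i"
        frame.columns.name = "j"
        return frame
    raise TypeError(f"unsupported table type {type(table).__name__}")


def export_matrix(table, dialect: str = "tsv", precision: int | None = None) -> str:
    """Serialize a DP table as TSV or JSON text."""
    frame = matrix_frame(table, precision=precision)
    if dialect == "tsv":
        return frame.to_csv(sep="\t")
    if dialect == "json":
        return json.dumps(
            {
                "index": list(frame.index),
                "columns": list(frame.columns),
                "values": frame.values.tolist(),
            }
        )
    raise ValueError(f"unknown dialect {dialect!r}")


def export_dotplot(plot: DotPlot, dialect: str = "tsv") -> str:
    """Dot-plot records as TSV (columns i, j, probability) or JSON."""
    if dialect == "tsv":
        frame = pd.DataFrame(plot.to_rows(), columns=["i", "j", "probability"])
        return frame.to_csv(sep="\t", index=False)
    if dialect == "json":
        return json.dumps(
            {
                "n": plot.n,
                "basepairs": plot.to_rows(),
                "unpaired": list(plot.unpaired),
            }
        )
    raise ValueError(f"unknown dialect {dialect!r}")


def serialize_config(**components) -> dict:
    """Flatten dataclass components into one reproducible config mapping."""
    out: dict[str, Any] = {}
    for name, comp in components.items():
        if dataclasses.is_dataclass(comp):
            for fld in dataclasses.fields(comp):
                out[f"{name}.{fld.name}"] = getattr(comp, fld.name)
        else:
            out[name] = comp
    return out
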