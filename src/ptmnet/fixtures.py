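"""Named reference networks and worked examples as loadable fixtures.

The catalog covers the elementary two-reaction motifs (enzyme activation,
two-step, branching, confluence), the single-reaction motifs (autocatalysis,
association-dissociation, dimer formation), the auto-activating mutually
inhibitory double-cycle network (a classic resettable bistable switch), the
N=10 MAPK cascade, the three-partition distance worked example, and the
default hyperparameter set.  Partitions ship as canonical JSON in the package
data directory and every fixture round-trips through the JSON reader/writer
unchanged.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path

from .bistability import ParameterPoint
from .config import SearchConfig
from .network import RateConstants
from .partitions import Partition, partition_from_json

__all__ = [
    "PARTITION_FIXTURES",
    "NON_SEARCHABLE",
    "fixture_names",
    "load_fixture",
    "load_supplementary_parameters",
]

#: partition fixtures shipped as JSON (name -> data file)
PARTITION_FIXTURES = {
    "fig1a": "fig1a.json",  # product of reaction 1 catalyzes reaction 2
    "fig1b": "fig1b.json",  # two-step reaction
    "fig1c": "fig1c.json",  # branching reaction
    "fig1d": "fig1d.json",  # confluence reaction
    "fig1e": "fig1e.json",  # autocatalysis (N=1)
    "fig1f": "fig1f.json",  # association-dissociation (N=1)
    "fig1g": "fig1g.json",  # dimer formation-separation (N=1)
    "fig2a": "fig2a.json",  # auto-activating mutually inhibitory network (N=4)
    "fig2b": "fig2b.json",  # MAPK cascade (N=10)
    "fig3A": "fig3A.json",  # distance worked example A
    "fig3B": "fig3B.json",  # distance worked example B
    "fig3C": "fig3C.json",  # distance worked example C
}

#: fixtures that are not valid search states for the default E1 -> P2 problem
#: (N < 4, or E1/P2 sharing a block)
NON_SEARCHABLE = frozenset(
    ["fig1a", "fig1b", "fig1c", "fig1d", "fig1e", "fig1f", "fig1g",
     "fig3A", "fig3B", "fig3C"]
)


def fixture_names() -> list[str]:
    return sorted(PARTITION_FIXTURES) + ["paper_config"]


def load_fixture(name: str) -> Partition | SearchConfig:
    """Load a named fixture: a partition, or the default search config."""
    if name == "paper_config":
        return SearchConfig()
    try:
        fname = PARTITION_FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
        ) from None
    text = resources.files("ptmnet.data").joinpath(fname).read_text()
    return partition_from_json(text)


def _parse_row(name: str, cells: list[str], n_reactions: int) -> ParameterPoint:
    need = 3 * n_reactions
    if len(cells) < need:
        raise ValueError(
            f"row {name!r}: expected at least {need} rate values "
            f"(a1..a{n_reactions}, d1..d{n_reactions}, k1..k{n_reactions}), "
            f"got {len(cells)}"
        )
    try:
        vals = [float(c) for c in cells]
    except ValueError as exc:
        raise ValueError(f"row {name!r}: non-numeric cell ({exc})") from None
    n = n_reactions
    rates = RateConstants(tuple(vals[:n]), tuple(vals[n:2 * n]), tuple(vals[2 * n:3 * n]))
    totals = {i: v for i, v in enumerate(vals[3 * n:])}
    return ParameterPoint(rates, totals)


def load_supplementary_parameters(
    path: str | Path, n_reactions: int = 4
) -> dict[str, ParameterPoint] | None:
    """Parse user-supplied kinetic parameter tables (optional data).

    Expects a CSV or XLSX whose rows are ``name, a1..aN, d1..dN, k1..kN
    [, totals...]``; header rows are skipped.  Returns None (a skip signal,
    not a failure) when the file is absent — these tables are optional inputs
    that are never downloaded and nothing in the test suite requires them.
    """
    path = Path(path)
    if not path.exists():
        return None
    rows: list[list[str]] = []
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        import openpyxl  # optional dependency (extra "xlsx")

        wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
        ws = wb.worksheets[0]
        for row in ws.iter_rows(values_only=True):
            rows.append(["" if c is None else str(c) for c in row])
    else:
        with open(path, newline="") as fh:
            rows = [list(r) for r in csv.reader(fh)]
    out: dict[str, ParameterPoint] = {}
    for row in rows:
        if not row or not row[0].strip():
            continue
        name = row[0].strip()
        cells = [c for c in row[1:] if str(c).strip() != ""]
        if not cells:
            continue
        try:
            float(cells[0])
        except ValueError:
            continue  # header row
        out[name] = _parse_row(name, cells, n_reactions)
    return out
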