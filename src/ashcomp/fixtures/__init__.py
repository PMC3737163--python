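"""Machine-readable transcriptions of the published feature tables and
constants for the two re-annotated genomes, with the small counting and
arithmetic helpers built on them.

Tables ship as TSV inside the package: re-annotation additions (``table1``,
where the two duplicated printed rows are deduplicated — see the file
header), removals (``table2``), tandem-duplication sets with per-genome copy
numbers (``table5``) and a ``constants`` key/value table (telomere unit,
introgression boundaries, headline counts).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_TABLES = ("table1", "table2", "table5", "constants")


def load_table(name: str) -> pd.DataFrame:
    if name not in _TABLES:
        raise KeyError(f"unknown table {name!r}; have {_TABLES}")
    ref = resources.files(__package__) / "data" / f"{name}.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def load_constants() -> dict[str, str]:
    df = load_table("constants")
    return dict(zip(df["key"], df["value"]))


def count_features(table: pd.DataFrame, feature_type: str) -> int:
    """Distinct feature records of a given type in a table1/table2-style table."""
    if "feature" not in table.columns:
        raise ValueError("table has no feature column")
    return int((table["feature"] == feature_type).sum())


_GENOME_COLUMN = {"A_gossypii": "copies_gossypii", "A_aceri": "copies_aceri"}


def count_tandem_sets(table5: pd.DataFrame, genome: str, min_copies: int = 2) -> int:
    """Number of duplication sets with >= min_copies tandem copies in a genome."""
    col = _GENOME_COLUMN.get(genome)
    if col is None:
        raise KeyError(f"unknown genome {genome!r}; have {sorted(_GENOME_COLUMN)}")
    return int((table5[col].astype(int) >= min_copies).sum())


def interval_length(start: int, end: int) -> int:
    """Span between two printed boundary coordinates (end - start)."""
    if start >= end:
        raise ValueError(f"need start < end, got {start} >= {end}")
    return end - start


def sequence_length(seq: str) -> int:
    if not seq:
        raise ValueError("empty sequence")
    return len(seq)


def rounded_percentage(numerator: int, denominator: int) -> int:
    """Integer percent, round half up (the printed-table convention)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    import math
    return math.floor(100 * numerator / denominator + 0.5)
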