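"""Literature-reported reference tables for angiogenin variants.

Bundled CSVs carry per-pair hydrogen-bond occupancies along the shortest
mutation-site→His114 paths, the Thr44–Thr80 / Asp116–Ser118 occupancies,
and the last-10 ns NLS (³¹RRR³³) SASA and enclosing-sphere volumes from
50 ns MD studies of WT angiogenin and six ALS-associated variants.  They
serve as fixed inputs: path-sum arithmetic, classifier checks and the
scenario generator all draw on them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_path_table",
    "path_occupancies",
    "load_special_pairs",
    "special_pair_occupancies",
    "load_nls_reference",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("trajmech.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_path_table() -> pd.DataFrame:
    """Per-pair occupancy (%) along each variant's shortest path.

    Columns: variant, donor_res, donor_name, acceptor_res, acceptor_name,
    occupancy_pct.  The two L35P branches are keyed 'L35P-Leu115' and
    'L35P-Thr44'.
    """
    return _read("path_occupancy.csv")


def path_occupancies(variant: str) -> dict[tuple[int, int], float]:
    """Ordered {(donor_res, acceptor_res): occupancy_pct} for one variant."""
    df = load_path_table()
    sub = df[df["variant"] == variant]
    if sub.empty:
        known = ", ".join(df["variant"].unique())
        raise KeyError(f"unknown variant {variant!r}; known: {known}")
    return {
        (int(r.donor_res), int(r.acceptor_res)): float(r.occupancy_pct)
        for r in sub.itertuples()
    }


def load_special_pairs() -> pd.DataFrame:
    """Thr44–Thr80 and Asp116–Ser118 occupancies (%) per variant."""
    return _read("special_pairs.csv")


def special_pair_occupancies(variant: str) -> tuple[float, float]:
    df = load_special_pairs()
    sub = df[df["variant"] == variant]
    if sub.empty:
        raise KeyError(f"unknown variant {variant!r}")
    row = sub.iloc[0]
    return float(row["thr44_thr80_pct"]), float(row["asp116_ser118_pct"])


def load_nls_reference() -> pd.DataFrame:
    """Last-10 ns per-residue NLS SASA (Å²), mean enclosing-sphere volume
    (Å³) and the experimentally established translocation outcome."""
    return _read("nls_reference.csv")
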