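import io

import pandas as pd
import pytest
from skbio import TreeNode

from frontassembly.core import OtuTable


@pytest.fixture
def four_tip_tree() -> TreeNode:
    """Balanced 4-tip tree with unit branches: d(A,B)=2, d(A,C)=4."""
    return TreeNode.read(io.StringIO("((A:1,B:1):1,(C:1,D:1):1);"))


def make_table(counts: dict, meta: dict | None = None) -> OtuTable:
    """Build an OtuTable from {sample_id: {otu: count}} plus metadata rows."""
    df = pd.DataFrame(counts).T.fillna(0).astype(int)
    if meta is None:
        meta = {
            sid: dict(season="March", station="F", depth="surface",
                      size_fraction="micro", replicate=1)
            for sid in df.index
        }
    mdf = pd.DataFrame(meta).T
    mdf.index.name = "sample_id"
    return OtuTable(df, mdf)


@pytest.fixture
def toy_survey() -> OtuTable:
    """Printed 10-OTU x 6-sample toy: 2 seasons x 3 stations, hand-counted.

    March totals 20000 reads (abundant > 20 reads, rare <= 2); July totals
    10000 (abundant > 10, rare <= 1).  o7 sits exactly on the March 0.1%
    boundary, o9 exactly on the July 0.01% boundary.
    """
    counts = {
        "March|O1": {"o1": 9000, "o2": 500, "o3": 1, "o5": 2, "o7": 10},
        "March|F": {"o1": 5000, "o4": 15, "o5": 3, "o7": 10, "o8": 1},
        "March|C1": {"o1": 5347, "o2": 100, "o6": 8, "o9": 3},
        "July|O1": {"o1": 50, "o7": 6000, "o10": 3},
        "July|F": {"o1": 80, "o3": 4, "o7": 3849, "o10": 6},
        "July|C1": {"o2": 6, "o9": 1, "o10": 1},
    }
    meta = {
        sid: dict(season=sid.split("|")[0], station=sid.split("|")[1],
                  depth="surface", size_fraction="micro", replicate=1)
        for sid in counts
    }
    return make_table(counts, meta)


@pytest.fixture
def trait_frame() -> pd.DataFrame:
    """Twelve-trait table of four rows used by the Gower hand examples."""
    base = dict(
        SizeMin=10.0, SizeMax=20.0, **{
            "Cell Cover": "silica", "Cell Shape": "elongated",
            "Cell Symmetry": "radial", "Cell Polarity": "isopolar",
            "Ingestion method": "none", "Symbiosis type": "none",
            "Presence of Spicule": 0, "Coloniality": 0, "Motility": 1,
            "Resting Stage": 0,
        },
    )
    rows = {"ref_a": dict(base), "ref_b": dict(base), "ref_c": dict(base),
            "ref_d": dict(base)}
    rows["ref_b"]["Cell Cover"] = "naked"  # one categorical mismatch vs ref_a
    rows["ref_c"]["SizeMin"] = 20.0  # numeric offset vs ref_a
    rows["ref_d"]["SizeMin"] = 50.0  # sets the SizeMin pool range to 40
    rows["ref_d"]["SizeMax"] = 60.0
    df = pd.DataFrame(rows).T
    for c in ("SizeMin", "SizeMax"):
        df[c] = df[c].astype(float)
    df.index.name = "taxref"
    return df
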