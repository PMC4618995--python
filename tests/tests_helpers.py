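"""Shared helpers for the test suite."""
import pandas as pd

from cnvrscan.calling import CNVRSet


def make_cnvrset_from_plan(plan, window=3000):
    """Treat the planted ground-truth regions as a called CNVR set."""
    df = plan.regions.copy()
    df["n_windows"] = (df["end"] - df["start"]) // window
    df["peak_tsd"] = 1.0
    df["mean_tsd"] = 1.0
    df["rows"] = [[] for _ in range(len(df))]
    total = int((df["end"] - df["start"]).sum()) if len(df) else 0
    return CNVRSet(regions=df, threshold=0.25, total_bp=total,
                   genome_fraction=0.0)
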