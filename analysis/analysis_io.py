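"""Shared I/O helpers for the numbered analysis drivers."""

from pathlib import Path

import pandas as pd

from cnvburden.cnv import CNVCall
from cnvburden.intervals import parse_region


def read_test_calls(path: Path) -> list[CNVCall]:
    """Read a filtered-call TSV written by 02_qc_filter.py."""
    df = pd.read_csv(path, sep="\t")
    return [
        CNVCall(r.sample_id, parse_region(r.region), r.cnv_type,
                int(r.n_probes), int(r.copy_number))
        for r in df.itertuples(index=False)
    ]
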