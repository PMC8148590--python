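"""Bundled small datasets.

``tantilla_run_table`` holds the published sequencing metadata of the six
Tantilla nigriceps Duvernoy's-gland libraries (read-pair and merged-read
counts per voucher) used by the run-summary statistics.
"""

from __future__ import annotations

import pandas as pd

from venomkit.readproc import SampleRunStats

_ROWS = [
    ("ASNHC-15178", "Hudspeth Co., TX", "F", 27_832_797, 22_093_170),
    ("ASNHC-15179", "Hudspeth Co., TX", "M", 28_872_668, 24_078_211),
    ("ASNHC-15180", "Duval Co., TX", "F", 22_736_233, 17_826_005),
    ("ASNHC-15181", "Hidalgo Co., NM", "F", 14_445_533, 10_648_351),
    ("ASNHC-15182", "Hidalgo Co., NM", "M", 8_088_121, 6_232_048),
    ("ASNHC-15183", "Hidalgo Co., NM", "M", 18_480_258, 15_030_748),
]


def tantilla_run_table() -> pd.DataFrame:
    return pd.DataFrame(_ROWS, columns=["sample_id", "locality", "sex", "read_pairs", "merged_reads"])


def tantilla_run_stats() -> list[SampleRunStats]:
    return [SampleRunStats(r[0], r[3], r[4]) for r in _ROWS]
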