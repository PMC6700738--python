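"""Bundled reference datasets.

The only dataset shipped is a published per-method stability ranking of
22 candidate reference genes (4 conventional housekeeping genes plus 18
miRNAs) from a qRT-PCR screen of mouse fecal samples.  It serves as the
worked example for the consensus stage: feeding its three rank columns
to :func:`refstab.consensus.aggregate_ranks` must reproduce the
published Average column (3 decimals) and comprehensive order.
"""

from __future__ import annotations

import pandas as pd

# gene, genorm_rank, normfinder_rank, bestkeeper_rank, average, comprehensive_rank
_PUBLISHED_ROWS = [
    ("mir-23a", 1, 3, 2, 2.0, 1),
    ("GAPDH", 1, 1, 6, 2.667, 2),
    ("let-7i", 3, 6, 1, 3.333, 3),
    ("mir-378", 4, 2, 5, 3.667, 4),
    ("mir-1224", 5, 4, 7, 5.333, 5),
    ("mir-155", 7, 7, 3, 5.667, 6),
    ("mir-574", 6, 9, 4, 6.333, 7),
    ("16S rRNA", 8, 5, 8, 7.0, 8),
    ("mir-29b", 9, 8, 11, 9.333, 9),
    ("let-7b", 10, 16, 9, 11.667, 10),
    ("mir-26b", 11, 17, 10, 12.667, 11),
    ("mir-141", 15, 11, 15, 13.667, 12),
    ("mir-200c", 16, 10, 18, 14.667, 13),
    ("mir-192", 17, 12, 16, 15.0, 14),
    ("let-7g", 13, 19, 13, 15.0, 15),
    ("mir-194", 12, 18, 17, 15.667, 16),
    ("let-7a", 14, 20, 14, 16.0, 17),
    ("mir-200a", 18, 14, 19, 17.0, 18),
    ("U6 snRNA", 19, 13, 20, 17.333, 19),
    ("mir-200b", 22, 22, 12, 18.667, 20),
    ("5s rRNA", 20, 15, 22, 19.0, 21),
    ("mir-15a", 21, 21, 21, 21.0, 22),
]


def published_stability_ranks() -> pd.DataFrame:
    """The published 22-gene consensus worked example.

    Columns ``genorm_rank, normfinder_rank, bestkeeper_rank`` are the
    inputs; ``average`` (3-decimal) and ``comprehensive_rank`` are the
    published aggregated outputs to check against.
    """
    return pd.DataFrame(
        _PUBLISHED_ROWS,
        columns=[
            "gene",
            "genorm_rank",
            "normfinder_rank",
            "bestkeeper_rank",
            "average",
            "comprehensive_rank",
        ],
    )
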