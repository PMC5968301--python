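"""Bundled worked example data.

``pumilus_group_case_study`` returns the published comparative
identifications of ten spacecraft-assembly archive isolates belonging to
the *Bacillus pumilus* taxonomic group (*B. pumilus*, *B. safensis*,
*B. australimaris*, *B. zhangzhouensis*): for each isolate the 16S rRNA
call with its percent identity, and the MALDI-TOF real-time-classification
hit with its log score.  Feeding these rows through the concordance
categorizer at the 2.2 threshold yields four species-concordant isolates,
three isolates confidently re-assigned by their MALDI identification, and
three potentially novel species.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["pumilus_group_case_study"]

_CASE_STUDY_ROWS = [
    # isolate, accession, 16S species, % identity, MALDI entry, log score
    ("PF9-10.2.1", "KT920027.1", "B. safensis", 100.0, "Bacillus safensis_FO36b^T", 2.30),
    ("PF9-10.1.1", "KT720019.1", "B. safensis", 100.0, "Bacillus safensis_FO36b^T", 2.22),
    ("MER_TA_110.2", "KT719518.1", "B. safensis", 99.4, "Bacillus safensis_FO36b^T", 2.32),
    ("AMY_31.2", "KT719925.1", "B. pumilus", 99.2, "Bacillus pumilus_DSM 27^T", 2.33),
    ("AMY_17.1", "KT719907.1", "B. pumilus", 99.8, "Bacillus australimaris_LMG_27697^T", 2.32),
    ("MER_178", "KT719762.1", "B. australimaris", 99.8, "Bacillus safensis_FO36b^T", 2.24),
    ("MER_114.2", "KT719690.1", "B. zhangzhouensis", 99.3, "Bacillus pumilus_DSM 27^T", 2.36),
    ("MSL_3001", "KT719852.1", "B. pumilus", 99.8, "Bacillus australimaris_LMG_27697^T", 2.19),
    ("IN_293", "MG881821", "B. australimaris", 99.8, "Bacillus safensis_FO36b^T", 2.17),
    ("V45.5", "KT720340.1", "B. pumilus", 99.8, "Bacillus pumilus_DSM 27^T", 2.03),
]


def pumilus_group_case_study() -> pd.DataFrame:
    """Ten B. pumilus-group isolates with 16S and MALDI-TOF identifications."""
    return pd.DataFrame(
        _CASE_STUDY_ROWS,
        columns=[
            "isolate_id", "accession", "species_16s", "identity_16s",
            "maldi_entry", "log_score",
        ],
    )
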