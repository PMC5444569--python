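"""GenBank rendering of recode results."""

from __future__ import annotations

import io as _io
import re

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .recode import RecodeResult


def recode_result_to_genbank(result: RecodeResult, name: str) -> str:
    """Render a recoded part with its edit/site/overhang annotations."""
    record = SeqRecord(
        Seq(result.sequence),
        id=name[:20],
        name=re.sub(r"[^A-Za-z0-9_.-]", "_", name)[:16],
        description=f"type IIS common-syntax part derived from {name}",
        annotations={"molecule_type": "DNA", "topology": "linear"},
    )
    for ftype, interval, label in result.features:
        record.features.append(
            SeqFeature(
                SimpleLocation(interval.start, interval.end, strand=1),
                type="misc_feature",
                qualifiers={"label": [label], "note": [ftype]},
            )
        )
    out = _io.StringIO()
    SeqIO.write(record, out, "genbank")
    return out.getvalue()
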