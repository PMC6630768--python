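import numpy as np
import pytest

from darkproteome.types import (
    CoverageInterval,
    Criterion,
    ProteinRecord,
)


def make_protein(acc="P1", length=10, **kw):
    return ProteinRecord(accession=acc, organism="test", length=length, **kw)


def interval(acc, start, end, criterion="A", source="s1"):
    return CoverageInterval(acc, start, end, Criterion(criterion), source)


@pytest.fixture
def protein():
    return make_protein()


# One complete UniProt flat-file record; the expected values asserted in
# tests were read off this text by hand.
DAT_RECORD = """\
ID   TEST1_HUMAN             Reviewed;         100 AA.
AC   P00001; Q99999;
DE   RecName: Full=Test protein 1;
CC   -!- SUBCELLULAR LOCATION: Membrane; Multi-pass membrane protein.
CC   -!- FUNCTION: Does test things in the membrane.
FT   TRANSMEM        5..27
FT                   /note="Helical"
FT   TRANSMEM        40..62
FT                   /note="Helical"
DR   PDB; 1ABC; X-ray; 2.00 A; A=5-60.
DR   PDB; 2XYZ; NMR; -; A/B=1-50, C=61-90.
DR   PDB; 3BAD; X-ray; 1.90 A; A=banana.
SQ   SEQUENCE   100 AA;  11111 MW;  0000000000000000 CRC64;
     MKTAYIAKQR QISFVKSHFS RQLEERLGLI EVQAPILSRV GDGTQDNLSG AEKAVQVKVK
     ALPDAQFEVV HSLAKWKRQT LGQHDFSAGE GLYTHMKALR
//
"""

DAT_RECORD_NO_PDB = """\
ID   TEST2_HUMAN             Reviewed;         50 AA.
AC   P00002;
DE   RecName: Full=Test protein 2;
SQ   SEQUENCE   50 AA;  5555 MW;  0000000000000000 CRC64;
     MKTAYIAKQR QISFVKSHFS RQLEERLGLI EVQAPILSRV GDGTQDNLSG
//
"""
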