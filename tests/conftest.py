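import pytest

import varcontext as vc
from varcontext.fixtures import EmbeddedRepeat, FixtureSpec, SpikedVariant, make_reference


@pytest.fixture(scope="session")
def gc7():
    """Reference with a (GC)7 tract at 123-136 (guarded flanks), plus the
    normalized GC deletion anchored at 122 and its ambiguity annotation."""
    spec = FixtureSpec(
        length=300, seed=7,
        repeats=[EmbeddedRepeat(motif="GC", copies=7, position=123)],
    )
    refs, truth = make_reference(spec)
    rec = vc.VariantRecord(
        "chr_fix", 122, refs["chr_fix"].slice(122, 124), refs["chr_fix"].base(122)
    )
    norm = vc.normalize(rec, refs)
    ann = vc.aligned_positions(norm, refs)
    return {"refs": refs, "truth": truth, "deletion": norm, "ann": ann}


@pytest.fixture()
def simple_refs():
    """Tiny hand-written contig: positions 99-105 spell GCATTCA."""
    seq = "T" * 98 + "GCATTCA" + "AGGTCCATGA" * 3
    refs = vc.ReferenceSet()
    refs["c"] = vc.ReferenceSequence("c", seq)
    return refs
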