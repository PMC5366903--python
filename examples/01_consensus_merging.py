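"""Merge parallel CNV calls from three algorithms into per-sample consensus
events.

Two same-type calls on one sample identify the same event when their
reciprocal overlap is >= 40%; an event is kept when >= 2 distinct callers
support it.  Calls from the confidence-reporting caller with a log Bayes
Factor below 5 are discarded first.
"""

from placnv import CnvCall, GenomicInterval, build_consensus, filter_by_confidence

calls = [
    # one duplication seen by all three callers with jittered breakpoints
    CnvCall("sample1", "caller_A", GenomicInterval("1", 1_000_000, 1_080_000), "dup"),
    CnvCall("sample1", "caller_B", GenomicInterval("1", 1_004_000, 1_075_000), "dup"),
    CnvCall("sample1", "caller_C", GenomicInterval("1", 998_000, 1_082_000), "dup", confidence=22.0),
    # a deletion seen by only one caller: never becomes a consensus event
    CnvCall("sample1", "caller_A", GenomicInterval("2", 5_000_000, 5_050_000), "del"),
    # a low-confidence call from the confidence-reporting caller: filtered out
    CnvCall("sample1", "caller_C", GenomicInterval("2", 9_000_000, 9_030_000), "del", confidence=3.1),
]

kept = filter_by_confidence(calls, "caller_C", min_conf=5.0)
print(f"{len(calls)} raw calls, {len(kept)} after the confidence filter")

consensus = build_consensus(kept, "sample1", min_reciprocal=0.4, min_callers=2)
for event in consensus:
    iv = event.interval
    print(
        f"consensus {event.cnv_type} {iv.chrom}:{iv.start_bp + 1}-{iv.end_bp} "
        f"({iv.length_bp / 1e3:.0f} kb), supported by "
        f"{', '.join(sorted(event.supporting_callers))}"
    )

# The single consensus event spans the union of its member calls; the lone
# deletion and the low-confidence call contribute nothing.
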