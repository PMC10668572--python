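"""Classify DMD exon rearrangements with the reading-frame rule.

An exon deletion/duplication whose coding span is a codon multiple keeps
the translational frame (predicting milder BMD); otherwise the frame is
lost (predicting DMD).
"""

from dmdspectrum import (
    classify_call,
    load_gene_model,
    parse_mutation_notation,
    predict_phenotype,
)

model = load_gene_model()  # packaged 79-exon Dp427m coding table

for notation in ["del 46-48", "del 7-43", "del 45-49", "dup 14-17", "del 51"]:
    call = parse_mutation_notation(notation)
    span = model.coding_span_length(call.first_exon, call.last_exon)
    frame = classify_call(call, model)
    print(
        f"{notation:>10}: {span:5d} coding nt (mod 3 = {span % 3}) -> "
        f"{frame.value:13s} -> predicted {predict_phenotype(frame).value}"
    )

# A span divisible by 3 prints in-frame/BMD; any remainder prints
# out-of-frame/DMD. del 7-43 (5760 nt) is the cohort's textbook in-frame
# giant deletion with a Becker phenotype.
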