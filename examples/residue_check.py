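"""Check sequences for the retinal-binding lysine (K296 homolog).

Maps the reference's ungapped position 296 through the alignment and
classifies every sequence at the homologous column.  A complete sequence
with another residue there is positively lysine-less; a sequence that
simply ends before the column is undetermined — the distinction that
separates "this opsin lost the lysine" from "the transcript is
incomplete".
"""

from opsin_dollo import classify_sequences, fixtures, summarize_calls

alignment, truth = fixtures.packaged_alignment()
calls = classify_sequences(alignment, truth.reference_id, truth.reference_position)
for call in calls:
    print(f"{call.seq_id:32} column {call.column}: {call.residue} -> {call.call.value}")
print("summary:", summarize_calls(calls)["counts"])

# Expected: the *_complete_nolys_* sequence is lysine_absent, the
# *_truncated_* one undetermined_truncated, the controls lysine_present.
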