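"""Render a small synthetic HDX study and inspect its ground truth.

Builds a three-state study (apo, Na+, Na+ + DA) with one concerted (EX1)
and one uncorrelated (EX2) peptide, writes the uptake table, spectra and
controls to ./example_study/, and prints the first uptake rows.
"""

from hdxkit import Peptide, PeptideModel, StudyDesign, render_study
from hdxkit.synthetic import ex1_site_model, ex2_site_model, random_protein

design = StudyDesign()  # 75.2% labeling; 0.25, 1, 10, 60, 480 min; n = 3
sequence = random_protein(80, seed=8)

pep1 = Peptide.from_sequence("pepA", sequence[9:25], 10)
pep2 = Peptide.from_sequence("pepB", sequence[39:55], 40)

# ligand binding slows the concerted opening of pepA (smaller k_op)
k_ops = {"apo": 0.016, "Na+": 0.0019, "Na+ + DA": 0.0005}
models = [
    PeptideModel(
        peptide=pep1,
        states={s: ex1_site_model(pep1.max_uptake, k_op=k) for s, k in k_ops.items()},
        back_exchange=0.2,
    ),
    PeptideModel(
        peptide=pep2,
        states={s: ex2_site_model(pep2.max_uptake, 0.003) for s in design.states},
        back_exchange=0.2,
    ),
]

tables = render_study(design, models, "example_study", seed=1)
print(tables.uptake.head(8).to_string(index=False))
print(f"\n{len(tables.envelopes)} spectra written; ground truth:")
for pid, rec in tables.truth.records.items():
    print(" ", pid, {s: r["regime"] for s, r in rec.items()})
# Each row is one replicate centroid mass; state ND (exposure 0) is the
# undeuterated reference and maxD the maximum-labeled back-exchange control.
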