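"""Drug repositioning over the curated cardiovascular example module.

Five diseases (cardiomyopathies, dilated and hypertrophic cardiomyopathy,
heart failure, rheumatoid arthritis) and their curated therapeutic drug
links. Drug_score = n_T / N is the fraction of the module a drug already
treats; drugs at or above 0.6 become repositioning candidates for the
module members they do not yet cover.
"""

from cdmnet import classify_module, repositioning_candidates
from cdmnet.datasets import cardiovascular_drug_table, cardiovascular_module

module = cardiovascular_module()
table = cardiovascular_drug_table()

classes = {d: "Cardiovascular Diseases" for d in module}
classes["RA"] = "Musculoskeletal Diseases"
cls = classify_module(module, classes)
print(f"Module class: {cls.label} (majority {cls.majority_fraction:.0%}; "
      f"off-class members: {', '.join(cls.minority)})")

candidates = repositioning_candidates(list(module), table, min_score=0.6)
print(f"\n{len(candidates)} drugs cover at least 60% of the module:")
print(f"{'drug':<42} {'score':>5}  uncovered (repositioning targets)")
for rec in candidates[:8]:
    targets = ", ".join(rec.uncovered) if rec.uncovered else "-"
    print(f"{rec.drug_name:<42} {float(rec.score):>5.2f}  {targets}")
print("...")
print("\nA drug scoring 0.8 with RA uncovered (e.g. Carvedilol, Ramipril)")
print("treats all four cardiovascular members and is a candidate for")
print("repositioning to rheumatoid arthritis.")
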