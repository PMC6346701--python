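"""Small curated example datasets.

Currently one dataset: the CTD-derived therapeutic indicator matrix for a
five-disease cardiovascular module (Cardiomyopathies, Dilated
Cardiomyopathy, Hypertrophic Cardiomyopathy, Heart Failure, Rheumatoid
Arthritis) and the 30 drugs with a therapeutic link to at least 60% of it.
Entered by hand from the curated association records; used by the worked
examples and the drug-scoring tests.
"""

from __future__ import annotations

from .io import DrugAssociationRecord

__all__ = ["cardiovascular_module", "cardiovascular_drug_table"]

#: module members: (id, full name)
_CARDIO_DISEASES = (
    ("CM", "Cardiomyopathies"),
    ("DCM", "Cardiomyopathy, Dilated"),
    ("HCM", "Cardiomyopathy, Hypertrophic"),
    ("HF", "Heart Failure"),
    ("RA", "Arthritis, Rheumatoid"),
)

#: (drug name, MeSH id, CM, DCM, HCM, HF, RA) therapeutic indicators
_CARDIO_DRUGS = (
    ("Losartan", "D019808", 1, 1, 1, 1, 1),
    ("Resveratrol", "C059514", 1, 1, 1, 1, 1),
    ("Carvedilol", "C043211", 1, 1, 1, 1, 0),
    ("Angiotensin-converting enzyme inhibitors", "D000806", 1, 0, 1, 1, 1),
    ("Metoprolol", "D008790", 1, 1, 1, 1, 0),
    ("Ramipril", "D017257", 1, 1, 1, 1, 0),
    ("Azathioprine", "D001379", 1, 0, 1, 1, 1),
    ("Prednisone", "D011241", 1, 0, 1, 1, 1),
    ("Benazepril", "C044946", 1, 0, 1, 1, 0),
    ("Enalapril", "D004656", 1, 0, 1, 1, 0),
    ("Dobutamine", "D004280", 1, 1, 1, 0, 0),
    ("Spironolactone", "D013148", 1, 0, 1, 1, 0),
    ("Amiodarone", "D000638", 1, 1, 1, 0, 0),
    ("Nifedipine", "D009543", 1, 1, 1, 0, 0),
    ("Torsemide", "C026116", 1, 0, 1, 1, 0),
    ("Candesartan cilexetil", "C077793", 1, 0, 1, 1, 0),
    ("Morphine", "D009020", 1, 0, 1, 0, 1),
    ("Dipyridamole", "D004176", 1, 0, 1, 1, 0),
    ("Hydralazine", "D006830", 1, 0, 1, 1, 0),
    ("Ceftriaxone", "D002443", 1, 0, 1, 0, 1),
    ("Dihydralazine", "D004078", 1, 0, 1, 1, 0),
    ("Diuretics", "D004232", 1, 0, 1, 1, 0),
    ("Enoximone", "D017335", 1, 0, 1, 1, 0),
    ("Rosiglitazone", "C089730", 0, 1, 1, 0, 1),
    ("Protein kinase inhibitors", "D047428", 0, 1, 1, 1, 0),
    ("Quinapril", "C041125", 0, 1, 1, 1, 0),
    ("Candesartan", "C081643", 0, 1, 1, 1, 0),
    ("Sulfinpyrazone", "D013442", 0, 1, 1, 0, 1),
    ("Drugs, Chinese herbal", "D004365", 0, 0, 1, 1, 1),
    ("Plant extracts", "D010936", 0, 0, 1, 1, 1),
)


def cardiovascular_module() -> tuple[str, ...]:
    """Member disease ids of the five-disease cardiovascular example module."""
    return tuple(d for d, _ in _CARDIO_DISEASES)


def cardiovascular_drug_table() -> list[DrugAssociationRecord]:
    """Therapeutic (marker T) associations of the cardiovascular example module."""
    diseases = cardiovascular_module()
    records = []
    for name, mesh_id, *flags in _CARDIO_DRUGS:
        for disease, flag in zip(diseases, flags):
            if flag:
                records.append(DrugAssociationRecord(mesh_id, name, disease, "T"))
    return records
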