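"""Assembly of the full 52-feature vector for one complex."""

from __future__ import annotations

from collections import OrderedDict

from .catalogue import FEATURE_CATALOGUE
from .classify import DUPLEX_MIN_PAIRED_FRACTION
from .dna import C1C1_RANGE, N1N3_RANGE, dna_feature_block
from .protein import DEFAULT_CLASS_TABLE, ResidueClassTable, protein_feature_block
from .structure import ComplexStructure


def extract_features(
    cs: ComplexStructure,
    folding_text: str | None = None,
    class_table: ResidueClassTable = DEFAULT_CLASS_TABLE,
    sasa_points: int = 960,
    duplex_min_paired_fraction: float = DUPLEX_MIN_PAIRED_FRACTION,
    n1n3_range: tuple[float, float] = N1N3_RANGE,
    c1c1_range: tuple[float, float] = C1C1_RANGE,
) -> "OrderedDict[str, float]":
    """The canonical feature vector, in catalogue order.

    Folding features (ensemble_diversity, mfe_frequency) are NaN unless
    adapter text from an external folding run is supplied.
    """
    values: dict[str, float] = {}
    values.update(protein_feature_block(cs, class_table, sasa_points))
    values.update(
        dna_feature_block(
            cs,
            folding_text=folding_text,
            duplex_min_paired_fraction=duplex_min_paired_fraction,
            n1n3_range=n1n3_range,
            c1c1_range=c1c1_range,
        )
    )
    missing = [name for name in FEATURE_CATALOGUE if name not in values]
    if missing:  # programming error guard, not a data condition
        raise RuntimeError(f"feature assembly incomplete: {missing}")
    return OrderedDict((name, values[name]) for name in FEATURE_CATALOGUE)
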