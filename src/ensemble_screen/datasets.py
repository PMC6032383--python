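"""Bundled example data.

The cross-docking example is a published 5x5 grid of Glide SP scores for
the co-crystallised ligands of five androgen-receptor structures (PDB IDs
3B66, 3G0W, 3V49, 4HLW, 2PNU) docked into all five receptor conformations;
N/A marks pairs the docking engine could not pose.  Each ligand's native
conformation shares its PDB ID.
"""

from __future__ import annotations

from importlib import resources

from .score_data import LigandLabels, ScoreMatrix, load_labels, load_score_matrix


def load_crossdock_example() -> tuple[ScoreMatrix, LigandLabels, dict[str, str]]:
    """The 5-ligand x 5-structure cross-docking grid.

    Returns
    -------
    (matrix, labels, native_map)
        ``native_map`` maps each ligand to its native receptor conformation
        (the structure it was crystallised in — here, the same PDB ID).
    """
    data = resources.files("ensemble_screen") / "data"
    with resources.as_file(data / "crossdock_scores.csv") as p:
        matrix = load_score_matrix(p)
    with resources.as_file(data / "crossdock_labels.csv") as p:
        labels = load_labels(p)
    native_map = {lig: lig for lig in matrix.ligand_ids}
    return matrix, labels, native_map
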