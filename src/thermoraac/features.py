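"""Assembly of the mixed feature matrix from its three descriptor families.

The default configuration concatenates, per sequence:

* the 188D physicochemical descriptor (original sequence),
* gapped dipeptide frequencies over the reduced alphabet
  (19² = 361 slots per gap, gaps 0..2 → 1083 columns),
* auto-cross covariance features (original sequence, 18 columns),

for a mixed vector of width 1289. The unreduced-dipeptide ablation swaps the
reduced dipeptide block for the 20-letter one (3 x 400 = 1200 columns).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .alphabet import ReductionScheme, builtin_scheme, reduce_sequence
from .dipeptides import feature_names as dipeptide_names
from .dipeptides import gapped_dipeptide_features
from .matrix import FeatureMatrix, FeatureMeta
from .physchem import ACCConfig, acc_features, acc_names, physchem188, physchem188_names
from .sequence_io import LabeledDataset, ProteinRecord

DEFAULT_FAMILIES = ("physchem188", "dipeptide", "acc")


def extract_features(
    dataset: LabeledDataset | Sequence[ProteinRecord],
    scheme: ReductionScheme | str = "susko19",
    max_gap: int = 2,
    families: Sequence[str] = DEFAULT_FAMILIES,
    original_dipeptides: bool = False,
    acc_config: ACCConfig | None = None,
) -> FeatureMatrix:
    """Extract the mixed feature matrix for a dataset.

    Parameters
    ----------
    dataset
        Labeled or unlabeled protein records.
    scheme
        Reduction scheme (name or object) used for the dipeptide family only;
        the physicochemical and ACC families always see the original sequence.
    max_gap
        Largest dipeptide gap λ (blocks for every λ in 0..max_gap).
    families
        Which descriptor families to include, in canonical order.
    original_dipeptides
        Ablation switch: compute dipeptides on the original 20-letter
        alphabet instead of the reduced one.
    """
    if isinstance(scheme, str):
        scheme = builtin_scheme(scheme)
    unknown = set(families) - set(DEFAULT_FAMILIES)
    if unknown:
        raise ValueError(f"unknown feature families: {sorted(unknown)}")
    if not families:
        raise ValueError("at least one feature family required")
    families = [f for f in DEFAULT_FAMILIES if f in families]

    dip_scheme = builtin_scheme("identity20") if original_dipeptides else scheme
    cfg = acc_config or ACCConfig()

    meta: list[FeatureMeta] = []
    if "physchem188" in families:
        meta += [FeatureMeta(n, "physchem188") for n in physchem188_names()]
    if "dipeptide" in families:
        meta += [
            FeatureMeta(n, "dipeptide", lam=int(n.split("|")[1]))
            for n in dipeptide_names(dip_scheme, max_gap)
        ]
    if "acc" in families:
        meta += [FeatureMeta(n, "acc") for n in acc_names(cfg)]

    records = list(dataset)
    rows = []
    for rec in records:
        blocks = []
        if "physchem188" in families:
            blocks.append(physchem188(rec))
        if "dipeptide" in families:
            reduced = reduce_sequence(rec, dip_scheme)
            blocks.append(
                gapped_dipeptide_features(reduced, dip_scheme, max_gap).values
            )
        if "acc" in families:
            blocks.append(acc_features(rec, cfg))
        rows.append(np.concatenate(blocks))

    labels = None
    if all(r.label is not None for r in records) and records:
        labels = np.array([r.label for r in records], dtype=int)
    return FeatureMatrix(
        np.vstack(rows), meta, [r.id for r in records], labels
    )
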