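"""End-to-end experiment recipes built from the library stages.

The central recipe is the spike-in mixture recovery: a classifier is
trained only on pure synthetic populations of the two reference
phenotypes, then mixtures at known composition are pushed through the
identical imaging/segmentation/feature pipeline and the predicted
per-class fractions are compared with the designed ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .classify import ClassifierSpec, quantify_mixture, train_classifier
from .features import FEATURE_NAMES_V1, compute_features
from .phantoms import (EPITHELIAL, MESENCHYMAL, PhenotypeModel, match_to_truth,
                       render_spike_in, spike_in_counts)
from .preprocess import extract_cells

__all__ = ["SpikeInResult", "featurize_spike_in", "spike_in_quantification"]


@dataclass
class SpikeInResult:
    fractions_true: list[float]
    fractions_predicted: list[float]
    n_cells_designed: int
    n_cells_detected: list[int]
    max_abs_deviation: float       # max over mixtures, absolute fraction
    method: str = "random_forest"
    train_fold_sizes: tuple[int, int] = (0, 0)
    details: dict = field(default_factory=dict)


def featurize_spike_in(p_mesenchymal: float, n_cells: int, seed: int,
                       models=(EPITHELIAL, MESENCHYMAL),
                       with_labels: bool = True):
    """Render a spike-in scene, run the full preprocessing chain and
    compute morphology features.

    Returns (X, labels, extraction) where X is an (n_detected, 15) feature
    matrix in the v1 feature order and labels are truth labels matched by
    nearest centroid (None where unmatched); labels is None when
    ``with_labels`` is false.
    """
    frames, truth, _ = render_spike_in(p_mesenchymal, n_cells, seed,
                                       models=models)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # short stacks reuse all frames
        extraction = extract_cells(frames)
    vectors = [compute_features(p) for p in extraction.patches]
    ok = [i for i, fv in enumerate(vectors) if fv.qc_pass]
    X = np.array([vectors[i].as_array(FEATURE_NAMES_V1) for i in ok])
    labels = None
    if with_labels:
        cents = np.array([extraction.patches[i].centroid for i in ok])
        fids = np.array([extraction.patches[i].frame_id for i in ok])
        labels = match_to_truth(cents, fids, truth)
    return X, labels, extraction


def spike_in_quantification(seed: int, n_train: int = 1000, n_mix: int = 1000,
                            fractions: tuple[float, ...] = (0.25, 0.5, 0.75),
                            models: tuple[PhenotypeModel, PhenotypeModel] = (EPITHELIAL, MESENCHYMAL),
                            method: str = "random_forest") -> SpikeInResult:
    """Spike-in mixture recovery experiment.

    Trains on ``n_train`` cells per pure population (mixture fractions 0
    and 1) and predicts the mesenchymal fraction in mixtures of ``n_mix``
    cells at each designed fraction; the headline number is the maximum
    absolute deviation between predicted and designed fractions.
    """
    ss = np.random.SeedSequence(seed)
    sub = [int(s) for s in ss.generate_state(2 + len(fractions)) % (2**31)]
    epi, mes = models

    X_parts, y_parts = [], []
    for p, s in ((0.0, sub[0]), (1.0, sub[1])):
        X, labels, _ = featurize_spike_in(p, n_train, s, models=models)
        keep = [i for i, l in enumerate(labels) if l is not None]
        X_parts.append(X[keep])
        y_parts.extend(labels[i] for i in keep)
    X_train = np.vstack(X_parts)
    y_train = np.asarray(y_parts)
    clf = train_classifier(X_train, y_train, ClassifierSpec(method=method, seed=seed))

    preds, trues, n_det = [], [], []
    for p, s in zip(fractions, sub[2:]):
        _, n_mes = spike_in_counts(p, n_mix)
        X, _, _ = featurize_spike_in(p, n_mix, s, models=models,
                                     with_labels=False)
        frac = quantify_mixture(clf, X)
        preds.append(frac.get(mes.name, 0.0))
        trues.append(n_mes / n_mix)
        n_det.append(X.shape[0])
    devs = [abs(a - b) for a, b in zip(preds, trues)]
    return SpikeInResult(
        fractions_true=trues, fractions_predicted=preds,
        n_cells_designed=n_mix, n_cells_detected=n_det,
        max_abs_deviation=float(max(devs)), method=method,
        train_fold_sizes=(int(np.sum(y_train == epi.name)),
                          int(np.sum(y_train == mes.name))),
        details={"per_mixture_deviation": devs})
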