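"""Waveform -> labeled 2-D example preparation.

A raw waveform is cut into ``n_elements`` overlapping windows ("waveform
elements"), each trimmed to start on a full pulse boundary and reshaped
row-major into a 2-D array whose rows are laser pulses and whose columns are
the samples within a pulse — turning the 1-D classification problem into an
image-classification one.  Rows are then decimated by a pulse-reduction
factor (the optical resolution covers several consecutive pulses, so most
rows are redundant), each element is z-scored, labeled from the ground-truth
cell annotations, and the dataset is shuffled and split 80/10/10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .simulate import LABELS, RawWaveform

__all__ = [
    "WaveformElement",
    "DatasetSplits",
    "DegenerateSpanError",
    "segment_waveform",
    "to_element",
    "reduce_pulses",
    "standardize_element",
    "label_element",
    "split_dataset",
    "iterate_batches",
    "prepare_dataset",
]

BLANK = LABELS["blank"]


class DegenerateSpanError(ValueError):
    """A span is too short to contain one full pulse after trimming."""


@dataclass
class WaveformElement:
    pixels: np.ndarray  # (pulse rows, samples per pulse)
    label: int
    source: tuple  # (waveform_id, start_sample, end_sample)


@dataclass
class DatasetSplits:
    """Disjoint train/validation/test index sets over a shuffled dataset."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    fractions: tuple
    split_seed: int

    @property
    def n_total(self) -> int:
        return len(self.train) + len(self.validation) + len(self.test)


def segment_waveform(n_samples: int, n_elements: int = 100,
                     overlap: float = 0.5) -> list[tuple[int, int]]:
    """Cut a waveform of ``n_samples`` into ``n_elements`` overlapping spans.

    The element length solves L * (n + (1 - n) * overlap) = T, so at the
    default 50% overlap L = 2T/(n+1) (each element is 2/101 of the waveform
    for n = 100).  Non-integer lengths are floored; span starts are spread
    evenly and the final span is anchored at the waveform end so total
    coverage is preserved.
    """
    if n_elements < 1:
        raise ValueError("n_elements must be >= 1")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    if n_samples < 1:
        raise ValueError("empty waveform")
    L = int(n_samples / (n_elements + (1 - n_elements) * overlap))
    if L < 1:
        raise ValueError("waveform too short for the requested segmentation")
    if n_elements == 1:
        return [(0, n_samples)]
    spans = []
    for i in range(n_elements):
        start = (i * (n_samples - L)) // (n_elements - 1)
        spans.append((start, start + L))
    return spans


def to_element(span_samples: np.ndarray, pulse_period_samples: int,
               start_phase: int = 0, *, standardize: bool = False) -> np.ndarray:
    """Reshape a 1-D span into (pulses x samples-per-pulse), row-major.

    ``start_phase`` is the phase of the span's first sample within the pulse
    cycle; leading samples before the next pulse boundary and the trailing
    partial pulse are trimmed so the element initiates from a full pulse.
    """
    period = int(pulse_period_samples)
    if period < 1:
        raise ValueError("pulse period must be >= 1")
    if not 0 <= start_phase < period:
        raise ValueError("start_phase must be in [0, period)")
    lead = (period - start_phase) % period
    n_pulses = (len(span_samples) - lead) // period
    if n_pulses < 1:
        raise DegenerateSpanError(
            "span shorter than one full pulse after trimming")
    element = np.asarray(span_samples)[lead:lead + n_pulses * period]
    element = element.reshape(n_pulses, period)
    if standardize:
        element = standardize_element(element)
    return element


def reduce_pulses(element: np.ndarray, reduction_factor: int = 40) -> np.ndarray:
    """Keep every ``reduction_factor``-th pulse row (indices 0, f, 2f, ...).

    The optical resolution spans many consecutive pulses, so dropping
    f - 1 of every f rows loses little information while shrinking the
    example f-fold.  Output rows = ceil(rows / f); columns unchanged.
    """
    f = int(reduction_factor)
    if f < 1:
        raise ValueError("reduction_factor must be >= 1")
    return element[::f]


def standardize_element(element: np.ndarray) -> np.ndarray:
    """Per-element z-score; an all-constant element maps to zeros."""
    mean = element.mean()
    sd = element.std()
    if sd == 0:
        return np.zeros_like(element, dtype=float)
    return (element - mean) / sd


def label_element(span: tuple[int, int], annotations: Sequence) -> int:
    """Label a span from the annotated cell centers it contains.

    The class of the cell whose center sample lies inside [start, end);
    blank if none.  With several centers inside, the one nearest the span
    midpoint wins (ties go to the earlier center).
    """
    start, end = span
    midpoint = (start + end) / 2.0
    best = None
    for cell, center in annotations:
        if start <= center < end:
            key = (abs(center - midpoint), center)
            if best is None or key < best[0]:
                best = (key, cell.label)
    if best is None:
        return BLANK
    return LABELS[best[1]]


def split_dataset(n_examples: int, fractions: tuple = (0.8, 0.1, 0.1),
                  seed: int = 0) -> DatasetSplits:
    """Seeded shuffle then contiguous 80/10/10 partition into disjoint
    train/validation/test index sets."""
    if n_examples < 1:
        raise ValueError("need at least one example")
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be three non-negative values")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    perm = np.random.default_rng(seed).permutation(n_examples)
    b1 = int(round(fractions[0] * n_examples))
    b2 = int(round((fractions[0] + fractions[1]) * n_examples))
    return DatasetSplits(
        train=perm[:b1],
        validation=perm[b1:b2],
        test=perm[b2:],
        fractions=tuple(fractions),
        split_seed=seed,
    )


def iterate_batches(X: np.ndarray, y: np.ndarray, batch_size: int = 64,
                    epoch_seed: int = 0) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield freshly shuffled batches partitioning (X, y); the final batch
    may be smaller.  Each epoch should pass a fresh ``epoch_seed``."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    n = len(X)
    if n == 0:
        raise ValueError("empty subset")
    perm = np.random.default_rng(epoch_seed).permutation(n)
    for i in range(0, n, batch_size):
        idx = perm[i:i + batch_size]
        yield X[idx], y[idx]


def prepare_dataset(waveforms: Sequence[RawWaveform], *,
                    n_elements: int = 100, overlap: float = 0.5,
                    reduction_factor: int = 40,
                    standardize: bool = True):
    """Segment, reshape, reduce, standardize and label a waveform cohort.

    All elements are cropped to a common row count (one less than the
    nominal pulses per element, since a random start phase costs up to one
    pulse) so the dataset stacks into a single array.

    Returns ``(X, y, manifest)``: X of shape (n, rows, columns) float32,
    y of shape (n,) uint8, and a per-element manifest DataFrame.
    """
    if not waveforms:
        raise ValueError("no waveforms given")
    period = waveforms[0].pulse_period_samples
    spans0 = segment_waveform(len(waveforms[0].samples), n_elements, overlap)
    L = spans0[0][1] - spans0[0][0]
    if L < 2 * period:
        raise ValueError("element length must cover at least two pulses")
    target_rows = L // period - 1

    examples, labels, rows = [], [], []
    for wf in waveforms:
        if wf.pulse_period_samples != period:
            raise ValueError("mixed pulse periods in cohort")
        spans = segment_waveform(len(wf.samples), n_elements, overlap)
        for start, end in spans:
            phase = (start + wf.start_phase_samples) % period
            el = to_element(wf.samples[start:end], period, phase)
            el = el[:target_rows]
            el = reduce_pulses(el, reduction_factor)
            if standardize:
                el = standardize_element(el)
            label = label_element((start, end), wf.annotations)
            examples.append(el.astype(np.float32))
            labels.append(label)
            rows.append({"waveform_id": wf.waveform_id, "start": start,
                         "end": end, "label": label})
    X = np.stack(examples)
    y = np.asarray(labels, dtype=np.uint8)
    return X, y, pd.DataFrame(rows)
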