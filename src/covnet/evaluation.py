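"""Confusion-matrix evaluation of an inferred network against a gold standard.

The pair universe must be declared, because the gold standard is a
directed TF -> target edge set while the inferred network is undirected:

* ``tf_by_target`` (default): the universe is every (tf, target) ordered
  pair with tf in the gold standard's TF list and target any other gene
  in the universe.  An undirected predicted edge {a, b} predicts the
  pair (a, b) when a is a TF, and (b, a) when b is a TF; edges touching
  no TF fall outside the universe and are ignored.
* ``all_pairs``: the universe is every unordered gene pair and the gold
  edges are symmetrized.  This is the natural mode for simulated truth,
  where every gene's neighborhood is known.
"""

from __future__ import annotations

from .datatypes import ConfusionCounts, DiagnosticMeasures, GoldStandard, Network

__all__ = ["confusion_vs_gold", "diagnostic_measures", "f1_score"]

UNIVERSE_MODES = ("tf_by_target", "all_pairs")


def confusion_vs_gold(net: Network, gold: GoldStandard,
                      universe_mode: str = "tf_by_target") -> ConfusionCounts:
    """Tally TP/FP/FN/TN for a network over the declared pair universe."""
    if universe_mode not in UNIVERSE_MODES:
        raise ValueError(f"unknown universe_mode {universe_mode!r}; "
                         f"expected one of {UNIVERSE_MODES}")
    universe_genes = set(gold.gene_universe)
    unknown = set(net.gene_ids) - universe_genes
    if unknown:
        raise ValueError(f"network genes outside gold universe: {sorted(unknown)[:5]}")

    edges = {(a, b) for a, b, _ in net.edge_list()}
    if universe_mode == "tf_by_target":
        tf_set = set(gold.tf_ids)
        universe_size = sum(
            len(universe_genes) - 1 for _ in tf_set
        )
        predicted: set[tuple[str, str]] = set()
        for a, b in edges:
            if a in tf_set:
                predicted.add((a, b))
            if b in tf_set:
                predicted.add((b, a))
        gold_edges = set(gold.edges)
    else:
        genes = sorted(universe_genes)
        universe_size = len(genes) * (len(genes) - 1) // 2
        predicted = {tuple(sorted(e)) for e in edges}
        gold_edges = {tuple(sorted(e)) for e in gold.edges}

    tp = len(predicted & gold_edges)
    fp = len(predicted - gold_edges)
    fn = len(gold_edges - predicted)
    tn = universe_size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn,
                           universe_size=universe_size,
                           universe_mode=universe_mode)


def diagnostic_measures(c: ConfusionCounts) -> DiagnosticMeasures:
    """Precision, recall, accuracy and specificity from confusion counts.

    Degenerate denominators yield 0 and are flagged by name rather than
    raising, so sweeping over sparse operating points stays total.
    """
    if c.universe_size <= 0:
        raise ValueError("universe_size must be positive")
    degenerate = set()

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            degenerate.add(name)
            return 0.0
        return num / den

    return DiagnosticMeasures(
        precision=ratio(c.tp, c.tp + c.fp, "precision"),
        recall=ratio(c.tp, c.tp + c.fn, "recall"),
        accuracy=(c.tp + c.tn) / c.universe_size,
        specificity=ratio(c.tn, c.tn + c.fp, "specificity"),
        degenerate=frozenset(degenerate),
    )


def f1_score(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall (0 when undefined)."""
    denom = 2 * c.tp + c.fp + c.fn
    return 2 * c.tp / denom if denom else 0.0
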