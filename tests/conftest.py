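import numpy as np
import pandas as pd
import pytest

from cnaexpr.copy_number import (
    assign_gene_values,
    call_copy_status,
    center_median,
    correct_amplification,
    segment_cbs,
)
from cnaexpr.synthetic import (
    CouplingSpec,
    EventSpec,
    GenomeSpec,
    default_events,
    generate_annotation,
    generate_expression,
    generate_probe_ratios,
    true_gene_ratios,
)


@pytest.fixture(scope="session")
def genome():
    return GenomeSpec()


@pytest.fixture(scope="session")
def annotation(genome):
    return generate_annotation(genome)


@pytest.fixture(scope="session")
def cohort(genome, annotation):
    """Small 8-tumour cohort with planted events, moderate noise, and the
    full copy-number stack already run (shared across tests; read-only)."""
    events = EventSpec(events=default_events(genome, 8, seed=0), noise_sd=0.15)
    matrix, truth_seg, copies = generate_probe_ratios(genome, events, seed=1)
    truth_cn = call_copy_status(true_gene_ratios(annotation, truth_seg))
    corrected = center_median(correct_amplification(matrix))
    segments = segment_cbs(corrected, seed=2)
    genecn = call_copy_status(assign_gene_values(segments, annotation))
    return {
        "events": events,
        "matrix": matrix,
        "corrected": corrected,
        "segments": segments,
        "truth_segments": truth_seg,
        "truth_cn": truth_cn,
        "genecn": genecn,
        "copies": copies,
    }


@pytest.fixture(scope="session")
def expression_pair(annotation, cohort):
    """(noisy expression matrix, truth table) coupled to the cohort truth."""
    coupling = CouplingSpec(seed=3)
    return generate_expression(annotation, cohort["truth_cn"], coupling)
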