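import numpy as np
import pytest

from phyto3d import (
    NodeDetectionConfig,
    SegmentationConfig,
    classification_suite,
    classify_second_order,
    compute_tensor_field,
    detect_nodes,
    extract_stem,
    generate_plant,
    internode_lengths,
    internode_suite,
    refine_first_order,
)


@pytest.fixture(scope="session")
def classification_suite_results():
    """Second-order and refined accuracy per seed on the default suite."""
    cfg = SegmentationConfig()
    rows = []
    for spec in classification_suite(range(1, 21)):
        cloud, truth = generate_plant(spec)
        field = compute_tensor_field(cloud, cfg.neighborhood)
        second = classify_second_order(field, cfg)
        refined = refine_first_order(second, field, cfg)
        rows.append(
            {
                "seed": spec.seed,
                "acc_second": float((second.labels == truth.labels).mean()),
                "acc_refined": float((refined.labels == truth.labels).mean()),
            }
        )
    return rows


@pytest.fixture(scope="session")
def internode_suite_results():
    """Estimated vs true first internode over the 10-30 cm suite."""
    cfg = SegmentationConfig()
    ncfg = NodeDetectionConfig()
    estimated, actual, node_counts = [], [], []
    for spec in internode_suite(range(1, 21)):
        cloud, truth = generate_plant(spec)
        field = compute_tensor_field(cloud, cfg.neighborhood)
        labels = refine_first_order(classify_second_order(field, cfg), field, cfg)
        stem, _idx, _frags = extract_stem(labels, cloud, ncfg)
        nodes = detect_nodes(stem, ncfg, cloud=cloud, labels=labels)
        report = internode_lengths(nodes, stem, ncfg)
        estimated.append(report.first_internode)
        actual.append(truth.first_internode)
        node_counts.append(len(nodes))
    return {
        "estimated": np.asarray(estimated),
        "actual": np.asarray(actual),
        "node_counts": node_counts,
    }
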