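import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

from vennkit import compute_partition, parse_count_lists, parse_lists

TABLE2_SAMPLE1 = ["Otu1", "Otu2", "Otu3", "Otu4", "Otu5", "Otu6", "Otu7"]
TABLE2_SAMPLE2 = ["Otu1", "Otu2", "Otu5", "Otu7", "Otu8", "Otu9"]
TABLE2_VALUES1 = [5, 15, 250, 20, 23, 58, 89]
TABLE2_VALUES2 = [90, 300, 10, 2, 45, 9]


@pytest.fixture
def lists_doc():
    """The two-sample OTU worked example, in lists format."""
    return {
        "series": [
            {"name": "sample1", "data": list(TABLE2_SAMPLE1)},
            {"name": "sample2", "data": list(TABLE2_SAMPLE2)},
        ]
    }


@pytest.fixture
def count_lists_doc():
    return {
        "series": [
            {
                "name": "sample1",
                "data": list(TABLE2_SAMPLE1),
                "values": list(TABLE2_VALUES1),
            },
            {
                "name": "sample2",
                "data": list(TABLE2_SAMPLE2),
                "values": list(TABLE2_VALUES2),
            },
        ]
    }


@pytest.fixture
def intersection_counts_doc():
    return {
        "series": [
            {
                "name": {"A": "sample 1", "B": "sample 2"},
                "data": {
                    "A": ["Otu3", "Otu4", "Otu6"],
                    "B": ["Otu8", "Otu9"],
                    "AB": ["Otu1", "Otu2", "Otu5", "Otu7"],
                },
            }
        ],
        "values": {"A": 3, "B": 2, "AB": 4},
    }


@pytest.fixture
def two_sample_series(lists_doc):
    return parse_lists(lists_doc)


@pytest.fixture
def two_sample_values_series(count_lists_doc):
    return parse_count_lists(count_lists_doc)


@pytest.fixture
def two_sample_table(two_sample_series):
    return compute_partition(two_sample_series)


@pytest.fixture
def rng():
    return np.random.default_rng(20140829)
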