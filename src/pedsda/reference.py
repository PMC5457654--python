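"""Published summary figures of the Kurume pedestrian-injury analysis.

These constants re-encode printed summary tables of the source study
(stratum sizes, subgroup sizes and severe percentages, and the fitted
cut-points) so that arithmetic consistency checks and the synthetic
generator's defaults can be driven without any external data.  The raw
registry itself was never deposited; only these printed aggregates are
available.

A known internal discrepancy of the printed material is encoded rather
than resolved: the tabulated severe percentage of the first older
subgroup reads 32.8 (which equals the older stratum's *overall* severe
rate), while the narrative gives 56.3 for the same subgroup; 56.3 is the
value that is arithmetically consistent with the subgroup sizes, since
the implied severe counts then sum exactly to the stratum total of 75.
"""

from __future__ import annotations

from .rounding import round_half_up

__all__ = [
    "OLDER_N", "OLDER_SEVERE", "WORKING_N", "WORKING_SEVERE",
    "OLDER_SUBGROUPS", "WORKING_SUBGROUPS",
    "OLDER_SUBGROUP_1_TABLE_VALUE", "OLDER_WIDE_ROAD_SUBGROUPS",
    "CUTPOINTS", "implied_severe_counts", "check_subgroup_reconciliation",
]

# Stratum totals.
OLDER_N = 229
OLDER_SEVERE = 75       # printed as 75 (32.8%)
WORKING_N = 316
WORKING_SEVERE = 31     # printed as 31 (9.8%)

#: Older-stratum subgroups in table column order: (n, severe %).
#: Rules: SES < 35.21 | SES >= 35.21 & narrow road | SES >= 35.21 & wide
#: road & aging > 20.3 | SES >= 35.21 & wide road & aging < 20.3.
OLDER_SUBGROUPS = ((32, 56.3), (68, 17.6), (55, 45.5), (74, 27.0))

#: The tabulated (inconsistent) severe % for the first older subgroup;
#: OLDER_SUBGROUPS carries the narrative (consistent) 56.3 instead.
OLDER_SUBGROUP_1_TABLE_VALUE = 32.8

#: The two wide-road older subgroups whose pooled severe rate was
#: reported as 34.9%.
OLDER_WIDE_ROAD_SUBGROUPS = ((55, 45.5), (74, 27.0))

#: Working-age subgroups: distance >= 132.84 & aging >= 21.05 | distance
#: >= 132.84 & aging < 21.05 | distance < 132.84.
WORKING_SUBGROUPS = ((66, 19.7), (219, 8.2), (31, 0.0))

#: Fitted cut-points of the source trees (not re-derivable without the
#: raw registry; used as planted-truth defaults by the generator).
CUTPOINTS = {
    "older_low_ses_prop": 35.21,
    "older_road_width_m": 5.5,   # "wide" = classes of 5.5 m per lane and up
    "older_aging_rate": 20.3,
    "working_network_distance_m": 132.84,
    "working_aging_rate": 21.05,
}


def implied_severe_counts(subgroups) -> list[int]:
    """Severe counts implied by printed (n, percent) pairs, half-up."""
    return [int(round_half_up(n * pct / 100.0, 0)) for n, pct in subgroups]


def check_subgroup_reconciliation(subgroups, stratum_severe: int) -> dict:
    """Verify that implied subgroup severe counts sum to the stratum total.

    Returns a report dict with the implied counts, their sum, the
    expected total and a boolean ``consistent`` flag.
    """
    counts = implied_severe_counts(subgroups)
    total = sum(counts)
    return {
        "implied_counts": counts,
        "implied_total": total,
        "expected_total": int(stratum_severe),
        "consistent": total == int(stratum_severe),
    }
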