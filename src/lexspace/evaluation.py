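"""Scoring of pipeline output against synthetic-truth sidecars.

The generators plant every extraction target and spatial signal with a known
answer; these helpers reconstruct the expected case table from a corpus truth
sidecar and score extraction output (precision/recall per field) or hot-spot
output (planted-cluster detection) against it.
"""

from __future__ import annotations

import numpy as np


def expected_cases(truth: list[dict], allowed_courts) -> dict[str, dict]:
    """Expected case table implied by a corpus truth sidecar.

    Judgments are grouped by their planted chain, members at disallowed
    courts dropped, and each surviving chain keyed by its earliest member's
    JID with attributes from the latest member (date order; the generator's
    monotone docket numbers break ties).
    """

    def order_key(row):
        parts = row["jid"].split(",")
        return (parts[4], int(parts[3]))

    chains: dict[str, list[dict]] = {}
    for row in truth:
        if row["court"] in allowed_courts:
            chains.setdefault(row["case_id"], []).append(row)
    out = {}
    for members in chains.values():
        members = sorted(members, key=order_key)
        out[members[0]["jid"]] = {
            "members": sorted(r["jid"] for r in members),
            "retained": members[-1],
        }
    return out


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float]:
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return precision, recall


def extraction_scores(records, truth: list[dict], allowed_courts) -> dict:
    """Precision/recall of the Article-19 flag, FACT span and district field.

    FACT spans count as correct only when byte-identical to the planted span;
    districts only when the resolved id equals the planted office's district.
    Cases planted as ambiguous (collisions without a county cue) are expected
    to resolve to nothing.
    """
    expected = expected_cases(truth, allowed_courts)
    got = {r.case_id: r for r in records}
    scores = {}

    tp = fp = fn = 0
    for cid, exp in expected.items():
        pred = cid in got and got[cid].article19
        true = exp["retained"]["article19"]
        tp += pred and true
        fp += pred and not true
        fn += true and not pred
    fp += sum(1 for cid, r in got.items() if r.article19 and cid not in expected)
    scores["article19_precision"], scores["article19_recall"] = _prf(tp, fp, fn)

    tp = fp = fn = 0
    for cid, exp in expected.items():
        truth_fact = exp["retained"]["fact_text"]
        pred_fact = got[cid].fact_text if cid in got else None
        if pred_fact is not None:
            if pred_fact == truth_fact:
                tp += 1
            else:
                fp += 1
                fn += truth_fact is not None
        elif truth_fact is not None:
            fn += 1
    scores["fact_precision"], scores["fact_recall"] = _prf(tp, fp, fn)

    tp = fp = fn = 0
    for cid, exp in expected.items():
        ret = exp["retained"]
        expect_district = (ret["district_id"]
                           if ret["expected_resolution"] == "resolved" else None)
        pred_district = got[cid].district_id if cid in got else None
        if pred_district is not None:
            if pred_district == expect_district:
                tp += 1
            else:
                fp += 1
                fn += expect_district is not None
        elif expect_district is not None:
            fn += 1
    scores["district_precision"], scores["district_recall"] = _prf(tp, fp, fn)
    return scores


def cluster_detected(location_trends, members, weights, min_frac: float = 0.5,
                     max_far_hot: float = 0.2) -> bool:
    """Did the emerging hot-spot analysis flag the planted cluster?

    Detection = at least ``min_frac`` of the planted block's districts end in
    a hot category while districts outside the block's queen-contiguity ring
    stay below ``max_far_hot`` hot fraction.
    """
    by_loc = location_trends.set_index("location")["category"]
    hot = by_loc.str.endswith("hot spot")
    members = set(members)
    block_frac = float(np.mean([hot[m] for m in members]))
    halo = {n for m in members for n in weights[m]}
    far = [d for d in by_loc.index if d not in halo]
    far_frac = float(np.mean([hot[d] for d in far])) if far else 0.0
    return block_frac >= min_frac and far_frac <= max_far_hot
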