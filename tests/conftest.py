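import random
from pathlib import Path

import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")

FIXTURES = Path(__file__).parent / "fixtures"


@pytest.fixture
def felis_backbone(tmp_path: Path) -> Path:
    """One-row backbone capturing the archaic-name failure mode:
    'Felis leo' is a historical synonym of the accepted 'Panthera leo'."""
    p = tmp_path / "backbone.tsv"
    p.write_text(
        "accepted_name\tsynonym\tstatus\n"
        "Panthera leo\tFelis leo\thomotypic\n",
        encoding="utf-8",
    )
    return p


@pytest.fixture
def small_backbone(tmp_path: Path) -> Path:
    """Three accepted names with mixed synonym clouds."""
    p = tmp_path / "small_backbone.tsv"
    p.write_text(
        "accepted_name\tsynonym\tstatus\n"
        "Panthera leo\tFelis leo\thomotypic\n"
        "Panthera leo\tLeo nobilis\theterotypic\n"
        "Orthriophis taeniurus\tElaphe taeniura\theterotypic\n"
        "Mus musculus\t\t\n",
        encoding="utf-8",
    )
    return p


def brute_force_ledger(syn_rows, tips, trait_names, normalize):
    """The literal list-of-lists matching algorithm, used as an oracle.

    For each trait name: a direct hit on a tip wins outright; otherwise
    every synonym list is scanned start to finish, and the tips touched
    by every list containing the name are unioned.  Exactly one tip =>
    recovered to that tip; several => ambiguous; none => unmatched.
    ``syn_rows`` is a list of name-lists (query first).
    """
    tip_by_key = {}
    for t in tips:
        tip_by_key.setdefault(normalize(t), t)
    ledger = []
    seen = set()
    for name in trait_names:
        key = normalize(name)
        if key in seen:
            continue
        seen.add(key)
        if key in tip_by_key:
            ledger.append((name, tip_by_key[key], "direct"))
            continue
        hit_tips = set()
        for row in syn_rows:
            row_keys = [normalize(n) for n in row]
            if key in row_keys:
                for k in row_keys:
                    if k in tip_by_key:
                        hit_tips.add(tip_by_key[k])
        if len(hit_tips) == 1:
            ledger.append((name, next(iter(hit_tips)), "recovered"))
        elif len(hit_tips) > 1:
            ledger.append((name, "", "ambiguous"))
        else:
            ledger.append((name, "", "unmatched"))
    return ledger


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240917)
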