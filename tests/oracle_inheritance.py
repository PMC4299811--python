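"""Independent truth-table implementation of the inheritance-model rules.

Used only as a test oracle. Works on plain dicts/tuples rather than the
package's domain types, and spells every rule out per model, so agreement
with ``pulsevar.inheritance`` is a genuine cross-check rather than a
tautology.

Configuration format:
    members: list of dicts {id, sex, affected, father, mother}
        sex in {male, female, unknown}; affected in {yes, no, unknown};
        father/mother are member ids or None.
    geno: member id -> allele tuple or None (unknown). Tuples contain 0/1;
        a 1-tuple is hemizygous.
"""

from __future__ import annotations


def _has_alt(gt):
    return gt is not None and any(a == 1 for a in gt)


def _is_het(gt):
    return gt is not None and len(gt) == 2 and gt[0] != gt[1]


def _is_hom_alt(gt):
    return gt is not None and all(a == 1 for a in gt)


def _member(members, mid):
    for m in members:
        if m["id"] == mid:
            return m
    return None


def oracle_single_models(contig, members, geno, reduced_penetrance=False):
    """Model set for one variant, by direct enumeration of the rules."""
    on_x = contig in ("X", "chrX")
    affected = [m for m in members if m["affected"] == "yes"]
    unaffected = [m for m in members if m["affected"] == "no"]
    if not affected:
        return set()
    if on_x:
        for m in members:
            if m["sex"] == "male" and _is_het(geno.get(m["id"])):
                return set()  # impossible genotype: no X model assigned
        candidates = ["XR", "XD"]
    else:
        candidates = ["AD", "AR_hom"]

    out = set()
    for model in candidates:
        if not _affected_fit(model, affected, geno):
            continue
        skip_carrier_check = reduced_penetrance and model in ("AD", "XD")
        if not skip_carrier_check and _unaffected_conflict(
            model, unaffected, geno
        ):
            continue
        inherited, de_novo, assessable = _transmission(
            model, on_x, members, affected, geno
        )
        if inherited:
            out.add(model)
        if de_novo and assessable:
            out.add(model + "_dn")
    return out


def _affected_fit(model, affected, geno):
    for m in affected:
        gt = geno.get(m["id"])
        if gt is None:
            continue  # unknown genotypes never exclude
        if model == "AD" or model == "XD":
            if not _has_alt(gt):
                return False
        elif model == "AR_hom":
            if not _is_hom_alt(gt):
                return False
        elif model == "XR":
            if m["sex"] == "male":
                if not _is_hom_alt(gt):
                    return False
            else:
                if not (_is_hom_alt(gt) and len(gt) == 2):
                    return False
    return True


def _unaffected_conflict(model, unaffected, geno):
    for m in unaffected:
        gt = geno.get(m["id"])
        if gt is None:
            continue
        if model == "AD" or model == "XD":
            if _has_alt(gt):
                return True
        elif model == "AR_hom":
            if _is_hom_alt(gt):
                return True
        elif model == "XR":
            if m["sex"] == "male":
                if _has_alt(gt):
                    return True
            else:
                if _is_hom_alt(gt) and len(gt) == 2:
                    return True
    return False


def _transmission(model, on_x, members, affected, geno):
    inherited = True
    de_novo = True
    assessable = False
    for m in affected:
        gt = geno.get(m["id"])
        if gt is None or not _has_alt(gt):
            continue
        father = _member(members, m["father"])
        mother = _member(members, m["mother"])
        if on_x and m["sex"] == "male":
            father = None  # a male's X comes from the mother
        parents = [p for p in (father, mother) if p is not None]
        if not parents:
            continue
        statuses = {}
        for p in parents:
            pgt = geno.get(p["id"])
            statuses[p["id"]] = None if pgt is None else _has_alt(pgt)
        if any(s is not None for s in statuses.values()):
            assessable = True
        if any(s is True for s in statuses.values()):
            de_novo = False
        # how many parental alleles does the affected genotype imply?
        two_sources = (
            model in ("AR_hom", "XR") and len(gt) == 2
            and not (on_x and m["sex"] == "male")
        )
        if two_sources:
            for p in parents:
                if statuses[p["id"]] is False:
                    inherited = False
        else:
            if all(s is False for s in statuses.values()):
                inherited = False
    return inherited, de_novo, assessable


def oracle_compound_pairs(members, geno1, geno2, reduced_penetrance=False):
    """Emitted pairs for two variants in one gene: (origins, de_novo) or
    None when no pair is emitted."""
    affected = [m for m in members if m["affected"] == "yes"]
    unaffected = [m for m in members if m["affected"] == "no"]
    supporters = [
        m for m in affected
        if _is_het(geno1.get(m["id"])) and _is_het(geno2.get(m["id"]))
    ]
    if not supporters:
        return None
    if not reduced_penetrance:
        for m in unaffected:
            if _has_alt(geno1.get(m["id"])) and _has_alt(geno2.get(m["id"])):
                return None
    for m in sorted(supporters, key=lambda x: x["id"]):
        o1, absent1 = _origin(members, m, geno1)
        o2, absent2 = _origin(members, m, geno2)
        if o1 == o2 and o1 in ("maternal", "paternal"):
            continue  # both members trace to the same parent: cis
        return (o1, o2), (absent1 or absent2)
    return None


def _origin(members, child, geno):
    father = _member(members, child["father"])
    mother = _member(members, child["mother"])
    f = None if father is None or geno.get(father["id"]) is None else _has_alt(
        geno[father["id"]]
    )
    m = None if mother is None or geno.get(mother["id"]) is None else _has_alt(
        geno[mother["id"]]
    )
    if m is True and f is False:
        return "maternal", False
    if f is True and m is False:
        return "paternal", False
    return "unknown", (f is False and m is False)
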