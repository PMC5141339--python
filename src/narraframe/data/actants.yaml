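# Default actant model: narrative agents and objects of the vaccination-
# exemption discussions, each with its associated (lowercase) word set.
# "exemptions" is a packaged addition so the plural surface form of the
# central object is matched without stemming nouns (see docs/methods.md).
actants:
  - name: Parents
    category: individual
    terms: [parents, parent, i, we, us, you]
  - name: Children
    category: individual
    terms: [child, kid, kids, children, daughter, daughters, son, sons,
            toddler, toddlers, kiddo, boy, dd, ds]
  - name: Medical professionals
    category: individual
    terms: [doctor, doctors, pediatrician, pediatricians, nurse, nurses,
            ped, md, dr]
  - name: Government
    category: institutional
    terms: [government, cdc, federal, feds, center for disease control,
            officials, politician, official, law]
  - name: Religious institutions
    category: institutional
    terms: [faith, religion, pastor, pastors, parish, parishes, church,
            churches, congregation, congregations, clergy]
  - name: Schools
    category: institutional
    terms: [teacher, teachers, preschools, preschool, school, schools,
            class, daycare, daycares, classes]
  - name: Pharmaceutical companies
    category: institutional
    terms: [pharma, big pharma, company, companies]
  - name: Vaccines
    category: object
    terms: [vaccines, vax, vaccine, vaccination, vaccinations, shots, shot,
            vaxed, unvax, unvaxed, nonvaxed, vaccinate, vaccinated, vaxes,
            vaxing, vaccinating, substances, ingredients]
  - name: Exemptions
    category: object
    terms: [exemption, exempt, exemptions]
  - name: VPDs
    category: object
    terms: [varicella, chickenpox, flu, whooping cough, tetanus, pertussis,
            hepatitis, polio, mumps, measles, diphtheria]
  - name: Adverse effects
    category: object
    terms: [autism, autistic, fever, fevers, reaction, reactions, infection,
            infections, inflammation, inflammations, pain, pains, bleeding,
            bruising, diarrhea]
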