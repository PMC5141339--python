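# Default relationship model: binary-opposition verb categories that become
# edge labels between actants.  Verbs are listed as surface base forms and
# stemmed at load time; "protect or threaten" appears once per applicability
# block, and "grant or withold" keeps its original spelling.
#
# applicability:
#   individual_institutional — both actants are individuals or institutions
#   object                   — at least one actant is an object
relationships:
  - name: Require or resist
    applicability: individual_institutional
    verbs: [force, require, need, follow, mandate]
  - name: Advise or question
    applicability: individual_institutional
    verbs: [recommend, tell, said, object, ask, learn, teach]
  - name: Protect or threaten
    applicability: individual_institutional
    verbs: [protect, injure, damage]
  - name: Employ or ignore
    applicability: individual_institutional
    verbs: [use, submit, ignore]
  - name: Accept or reject
    applicability: individual_institutional
    verbs: [vaccinate, unvaccinate, vax, unvax, receive, have, had, get,
            inject, exclude, allow, exempt, believe, receive, request, deny,
            accept]
  - name: Attend or avoid
    applicability: individual_institutional
    verbs: [enter, enroll, attend, go, send, homeschool]
  - name: Seek or aver
    applicability: object
    verbs: [seek, file, sign, claim, submit, need, exercise, lie, claim]
  - name: Grant or withold
    applicability: object
    verbs: [accept, approve, get, abuse, grant, oppose, deny]
  - name: Protect or threaten
    applicability: object
    verbs: [protect, injure, damage]
  - name: Cause or not cause
    applicability: object
    verbs: [expose, get, contract, cause, develop, suffer, die, vomit,
            diagnose]
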