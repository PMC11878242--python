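# Synthetic SMQ catalog for biliary disorders.
#
# The hierarchy topology (one root, nine sub-SMQs) mirrors the standard
# MedDRA grouping of biliary-disorder queries; the preferred-term lists are
# SYNTHETIC stand-ins written for testing, not the licensed MedDRA v24.0
# term lists, which cannot be redistributed. Supply a real catalog in the
# same format for production use.
- name: biliary disorders
  parent: null
  terms: []
- name: biliary malignant tumours
  parent: biliary disorders
  terms:
    - bile duct cancer
    - cholangiocarcinoma
    - gallbladder cancer
    - { pt: biliary cancer metastatic, scope: broad }
- name: biliary neoplasms benign (incl cysts and polyps)
  parent: biliary disorders
  terms:
    - bile duct adenoma
    - gallbladder polyp
    - biliary cyst
- name: biliary system related investigations, signs and symptoms
  parent: biliary disorders
  terms:
    - blood bilirubin increased
    - jaundice
    - { pt: hepatic enzyme increased, scope: broad }
    - biliary colic
- name: biliary tract disorders
  parent: biliary disorders
  terms:
    - bile duct obstruction
    - bile duct stenosis
    - cholestasis
    - biliary dyskinesia
- name: biliary tumours of unspecified malignancy
  parent: biliary disorders
  terms:
    - biliary neoplasm
    - gallbladder neoplasm
- name: congenital biliary disorders
  parent: biliary disorders
  terms:
    - biliary atresia
    - choledochal cyst congenital
- name: gallbladder related disorders
  parent: biliary disorders
  terms:
    - cholecystitis
    - cholecystitis acute
    - cholecystitis chronic
    - gallbladder disorder
    - gallbladder oedema
- name: gallstone related disorders
  parent: biliary disorders
  terms:
    - cholelithiasis
    - cholecystolithiasis
    - choledocholithiasis
    - gallbladder calculus
- name: infectious biliary disorders
  parent: biliary disorders
  terms:
    - cholangitis
    - cholangitis acute
    - cholecystitis infective
    - biliary sepsis
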