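format-version: 1.2
data-version: triotriage/2024-01
ontology: hpo-mini-synthetic
remark: Synthetic miniature phenotype ontology for tests and fixtures. HP-style identifiers and a DAG of top-level organ-system categories with representative descendant terms; NOT the Human Phenotype Ontology, only shaped like it.

[Term]
id: HP:0000001
name: All

[Term]
id: HP:0000924
name: Abnormality of the skeletal system
is_a: HP:0000001 ! All

[Term]
id: HP:0001626
name: Abnormality of the cardiovascular system
is_a: HP:0000001 ! All

[Term]
id: HP:0000707
name: Abnormality of the nervous system
is_a: HP:0000001 ! All

[Term]
id: HP:0000119
name: Abnormality of the genitourinary system
is_a: HP:0000001 ! All

[Term]
id: HP:0000152
name: Abnormality of head and neck
is_a: HP:0000001 ! All

[Term]
id: HP:0040064
name: Abnormality of limbs
is_a: HP:0000001 ! All

[Term]
id: HP:0002086
name: Abnormality of the respiratory system
is_a: HP:0000001 ! All

[Term]
id: HP:0025031
name: Abnormality of the digestive system
is_a: HP:0000001 ! All

[Term]
id: HP:0001574
name: Abnormality of the integument
is_a: HP:0000001 ! All

[Term]
id: HP:0000818
name: Abnormality of the endocrine system
is_a: HP:0000001 ! All

[Term]
id: HP:0002715
name: Abnormality of the immune system
is_a: HP:0000001 ! All

[Term]
id: HP:0000478
name: Abnormality of the eye
is_a: HP:0000001 ! All

[Term]
id: HP:0012759
name: Neurodevelopmental abnormality
is_a: HP:0000707 ! Abnormality of the nervous system

[Term]
id: HP:0001627
name: Abnormal heart morphology
is_a: HP:0001626 ! Abnormality of the cardiovascular system

[Term]
id: HP:0012443
name: Abnormality of brain morphology
is_a: HP:0000707 ! Abnormality of the nervous system

[Term]
id: HP:0002652
name: Skeletal dysplasia
is_a: HP:0000924 ! Abnormality of the skeletal system

[Term]
id: HP:0003026
name: Short long bone
is_a: HP:0000924 ! Abnormality of the skeletal system
is_a: HP:0040064 ! Abnormality of limbs

[Term]
id: HP:0000774
name: Narrow chest
is_a: HP:0000924 ! Abnormality of the skeletal system
is_a: HP:0002086 ! Abnormality of the respiratory system

[Term]
id: HP:0001762
name: Talipes equinovarus
is_a: HP:0040064 ! Abnormality of limbs
is_a: HP:0000924 ! Abnormality of the skeletal system

[Term]
id: HP:0005180
name: Tricuspid regurgitation
is_a: HP:0001627 ! Abnormal heart morphology

[Term]
id: HP:0010880
name: Increased nuchal translucency
is_a: HP:0001626 ! Abnormality of the cardiovascular system

[Term]
id: HP:0001631
name: Atrioventricular septal defect
is_a: HP:0001627 ! Abnormal heart morphology

[Term]
id: HP:0001629
name: Ventricular septal defect
is_a: HP:0001627 ! Abnormal heart morphology

[Term]
id: HP:0001660
name: Truncus arteriosus
is_a: HP:0001627 ! Abnormal heart morphology

[Term]
id: HP:0011611
name: Interrupted aortic arch
is_a: HP:0001627 ! Abnormal heart morphology

[Term]
id: HP:0001696
name: Cardiac malposition
is_a: HP:0001626 ! Abnormality of the cardiovascular system

[Term]
id: HP:0001392
name: Abnormality of the liver
is_a: HP:0025031 ! Abnormality of the digestive system

[Term]
id: HP:0012437
name: Abdominal situs inversus
is_a: HP:0025031 ! Abnormality of the digestive system

[Term]
id: HP:0002021
name: Pyloric stenosis
is_a: HP:0025031 ! Abnormality of the digestive system

[Term]
id: HP:0002575
name: Tracheoesophageal fistula
is_a: HP:0025031 ! Abnormality of the digestive system
is_a: HP:0002086 ! Abnormality of the respiratory system

[Term]
id: HP:0010442
name: Polydactyly
is_a: HP:0040064 ! Abnormality of limbs
is_a: HP:0000924 ! Abnormality of the skeletal system

[Term]
id: HP:0001159
name: Syndactyly
is_a: HP:0040064 ! Abnormality of limbs
is_a: HP:0000924 ! Abnormality of the skeletal system

[Term]
id: HP:0002817
name: Abnormality of the upper limb
is_a: HP:0040064 ! Abnormality of limbs

[Term]
id: HP:0002804
name: Arthrogryposis multiplex congenita
is_a: HP:0040064 ! Abnormality of limbs
is_a: HP:0000924 ! Abnormality of the skeletal system

[Term]
id: HP:0000871
name: Panhypopituitarism
is_a: HP:0000818 ! Abnormality of the endocrine system

[Term]
id: HP:0002119
name: Ventriculomegaly
is_a: HP:0012443 ! Abnormality of brain morphology

[Term]
id: HP:0001274
name: Agenesis of corpus callosum
is_a: HP:0012443 ! Abnormality of brain morphology

[Term]
id: HP:0001989
name: Fetal akinesia sequence
is_a: HP:0000707 ! Abnormality of the nervous system

[Term]
id: HP:0001250
name: Seizure
is_a: HP:0012759 ! Neurodevelopmental abnormality

[Term]
id: HP:0002069
name: Bilateral tonic-clonic seizure
is_a: HP:0001250 ! Seizure

[Term]
id: HP:0010818
name: Generalized tonic-clonic seizure
is_a: HP:0001250 ! Seizure

[Term]
id: HP:0001249
name: Intellectual disability
is_a: HP:0012759 ! Neurodevelopmental abnormality

[Term]
id: HP:0001328
name: Specific learning disability
is_a: HP:0012759 ! Neurodevelopmental abnormality

[Term]
id: HP:0000202
name: Orofacial cleft
is_a: HP:0000152 ! Abnormality of head and neck

[Term]
id: HP:0011297
name: Abnormal digit morphology
is_a: HP:0040064 ! Abnormality of limbs

[Term]
id: HP:0002721
name: Immunodeficiency
is_a: HP:0002715 ! Abnormality of the immune system

[Term]
id: HP:0004313
name: Decreased circulating antibody level
is_a: HP:0002715 ! Abnormality of the immune system

[Term]
id: HP:0000252
name: Microcephaly
is_a: HP:0000707 ! Abnormality of the nervous system
is_a: HP:0000152 ! Abnormality of head and neck

[Term]
id: HP:0001999
name: Abnormal facial shape
is_a: HP:0000152 ! Abnormality of head and neck

[Term]
id: HP:0000062
name: Ambiguous genitalia
is_a: HP:0000119 ! Abnormality of the genitourinary system

[Term]
id: HP:0000104
name: Renal agenesis
is_a: HP:0000119 ! Abnormality of the genitourinary system

[Term]
id: HP:0000003
name: Multicystic kidney dysplasia
is_a: HP:0000119 ! Abnormality of the genitourinary system

[Term]
id: HP:0000772
name: Abnormal rib morphology
is_a: HP:0000924 ! Abnormality of the skeletal system

[Term]
id: HP:0000925
name: Abnormality of the vertebral column
is_a: HP:0000924 ! Abnormality of the skeletal system

[Term]
id: HP:0002650
name: Scoliosis
is_a: HP:0000924 ! Abnormality of the skeletal system

[Term]
id: HP:0001363
name: Craniosynostosis
is_a: HP:0000924 ! Abnormality of the skeletal system
is_a: HP:0000152 ! Abnormality of head and neck

[Term]
id: HP:0000347
name: Micrognathia
is_a: HP:0000152 ! Abnormality of head and neck
is_a: HP:0000924 ! Abnormality of the skeletal system

[Term]
id: HP:0000528
name: Anophthalmia
is_a: HP:0000478 ! Abnormality of the eye

[Term]
id: HP:0000957
name: Cafe-au-lait spot
is_a: HP:0001574 ! Abnormality of the integument

[Term]
id: HP:0001067
name: Neurofibromas
is_a: HP:0001574 ! Abnormality of the integument
is_a: HP:0000707 ! Abnormality of the nervous system

[Term]
id: HP:0000256
name: Macrocephaly
is_a: HP:0000152 ! Abnormality of head and neck
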