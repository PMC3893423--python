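term,class
insulin,insulin
lantus,insulin
glargine,insulin
levemir,insulin
detemir,insulin
novorapid,insulin
aspart,insulin
humalog,insulin
lispro,insulin
apidra,insulin
glulisine,insulin
actrapid,insulin
humulin,insulin
protaphane,insulin
isophane,insulin
mixtard,insulin
novomix,insulin
monotard,insulin
ultratard,insulin
hypurin,insulin
metformin,biguanide
diabex,biguanide
diaformin,biguanide
glucophage,biguanide
formet,biguanide
glucomet,biguanide
metex,biguanide
gliclazide,sulphonylurea
diamicron,sulphonylurea
nidem,sulphonylurea
glyade,sulphonylurea
glimepiride,sulphonylurea
amaryl,sulphonylurea
aylide,sulphonylurea
glibenclamide,sulphonylurea
daonil,sulphonylurea
glimel,sulphonylurea
glipizide,sulphonylurea
minidiab,sulphonylurea
melizide,sulphonylurea
pioglitazone,thiazolidinedione
actos,thiazolidinedione
rosiglitazone,thiazolidinedione
avandia,thiazolidinedione
acarbose,alpha_glucosidase_inhibitor
glucobay,alpha_glucosidase_inhibitor
sitagliptin,dpp4_inhibitor
januvia,dpp4_inhibitor
vildagliptin,dpp4_inhibitor
galvus,dpp4_inhibitor
glucovance,premixed_oha
avandamet,premixed_oha
janumet,premixed_oha
exenatide,exenatide
byetta,exenatide
repaglinide,meglitinide
novonorm,meglitinide
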